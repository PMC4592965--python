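"""Independent brute-force oracle for the minimum alignment penalty.

Enumerates alignment configurations directly from their run-length structure
(diagonal exact-match runs and sliding mismatch windows) instead of dynamic
programming, so it shares no code path with the production aligner.

Under the default penalty configuration (mismatch 30, gap 40 + 6L, cap 60) any
reportable alignment is either ungapped (mismatches only) or carries exactly
one gap of length <= 3 with zero mismatches: two gaps cost >= 92 and a gap
plus a mismatch costs >= 76, both over the cap, so enumerating these two
families is exhaustive for penalties within the cap.
"""

from __future__ import annotations

MISMATCH = 30
GAP_OPEN = 40
GAP_EXTEND = 6
CAP = 60
MIN_CORE = 15


def oracle_min_penalty(read: str, hairpin: str, min_core: int = MIN_CORE) -> int | None:
    """Minimum penalty over every admissible alignment, or None if none <= cap."""
    m, n = len(read), len(hairpin)
    if m < min_core or n == 0:
        return None
    best: int | None = None

    def offer(p: int) -> None:
        nonlocal best
        if p <= CAP and (best is None or p < best):
            best = p

    # diagonal d: read[i] pairs hairpin[i + d]
    diagonals = range(-(m - 1), n)

    def diag_mismatches(d: int) -> tuple[int, list[bool]]:
        lo = max(0, -d)
        hi = min(m, n - d)
        return lo, [read[i] != hairpin[i + d] or read[i] == "N" for i in range(lo, hi)]

    # ungapped: minimum mismatch count over any window of >= min_core read bases;
    # the minimum over longer windows is never below the best min_core-window
    for d in diagonals:
        lo, mm = diag_mismatches(d)
        if len(mm) < min_core:
            continue
        window = sum(mm[:min_core])
        offer(MISMATCH * window)
        for i in range(min_core, len(mm)):
            window += mm[i] - mm[i - min_core]
            offer(MISMATCH * window)

    # one mismatch-free gap of length L: a clean prefix run on one diagonal
    # joined to a clean suffix run on the shifted diagonal
    def clean_runs(d: int) -> tuple[list[int], list[int]]:
        # end_run[i]: clean run length ending at read index i (inclusive);
        # start_run[i]: clean run length starting at read index i
        lo, mm = diag_mismatches(d)
        end_run = [0] * m
        start_run = [0] * m
        run = 0
        for k, bad in enumerate(mm):
            run = 0 if bad else run + 1
            end_run[lo + k] = run
        run = 0
        for k in range(len(mm) - 1, -1, -1):
            run = 0 if mm[k] else run + 1
            start_run[lo + k] = run
        return end_run, start_run

    runs = {d: clean_runs(d) for d in diagonals}
    for L in (1, 2, 3):
        cost = GAP_OPEN + GAP_EXTEND * L
        if cost > CAP:
            continue
        for d in diagonals:
            end_run, _ = runs[d]
            # deletion: hairpin bases [p+d, p+d+L) skipped; suffix on diagonal d+L
            if d + L in runs:
                _, start_after = runs[d + L]
                for p in range(1, m):
                    if end_run[p - 1] >= 1 and start_after[p] >= 1:
                        if end_run[p - 1] + start_after[p] >= min_core:
                            offer(cost)
            # insertion: read bases [p, p+L) unaligned; suffix on diagonal d-L
            if d - L in runs:
                _, start_after = runs[d - L]
                for p in range(1, m - L):
                    if end_run[p - 1] >= 1 and start_after[p + L] >= 1:
                        if end_run[p - 1] + L + start_after[p + L] >= min_core:
                            offer(cost)
    return best
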