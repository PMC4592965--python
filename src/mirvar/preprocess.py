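"""Quality filtering, error-tolerant 3' adapter trimming, and read collapsing.

The trimming model mirrors small-RNA library structure: a short insert followed by
a 3' sequencing adapter.  An adapter occurrence is either the full adapter found
internally or an adapter prefix running to the read's 3' end; occurrences of
length >= ``min_adapter_len`` matched with at most ``max_errors`` unit-cost edits
(mismatch, insertion, deletion) qualify, and the read is truncated at the leftmost
qualifying occurrence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from mirvar.formats import SequenceRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct clean-read sequence and the number of raw reads supporting it.

    The uid has the form "XXX-YYY" where XXX is a unique serial number and YYY
    is the support count.
    """

    uid: str
    sequence: str
    count: int


@dataclass(frozen=True)
class TrimSettings:
    adapter: str | None = None
    max_errors: int = 1
    min_adapter_len: int = 10
    min_read_len: int = 15
    skip_trimming: bool = False

    def __post_init__(self) -> None:
        if self.adapter is not None and len(self.adapter) < self.min_adapter_len:
            raise ValueError(
                f"adapter length {len(self.adapter)} < min_adapter_len {self.min_adapter_len}"
            )


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read.

    ``status`` is 'trimmed', 'no_adapter', or 'too_short'; ``read`` is None
    exactly when the read was dropped ('too_short').
    """

    status: str
    read: SequenceRead | None
    adapter_start: int | None = None


def quality_filter(
    reads: Iterable[SequenceRead], min_quality: int = 20, min_fraction: float = 0.95
) -> tuple[list[SequenceRead], int]:
    """Keep reads whose fraction of bases at Phred >= ``min_quality`` is >= ``min_fraction``.

    Returns (kept reads, number dropped).  Boundary inclusive: a 20-base read
    with exactly 19 passing bases (95%) is kept at the defaults.
    """
    kept: list[SequenceRead] = []
    n_dropped = 0
    for read in reads:
        n = len(read)
        if n == 0:
            n_dropped += 1
            continue
        n_good = sum(1 for q in read.qualities if q >= min_quality)
        if n_good >= min_fraction * n - 1e-9:
            kept.append(read)
        else:
            n_dropped += 1
    return kept, n_dropped


def _match_errors(read: str, pos: int, adapter: str, max_errors: int) -> tuple[int, int] | None:
    """Try to match ``adapter`` starting at ``read[pos:]`` with a banded edit DP.

    Returns (errors, matched_adapter_length) for the best qualifying occurrence
    at this position, or None.  An occurrence is the full adapter matched
    internally, or any adapter prefix that consumes the read to its 3' end.
    Preference at one position: fewer errors, then longer adapter match.
    N matches nothing.
    """
    tail = read[pos:]
    m, a = len(tail), len(adapter)
    if a == 0:
        return None
    band = max_errors
    # prev[j] = edit distance aligning adapter[:i] against tail[:j]; the
    # occurrence must start exactly at pos (a leading read-base insertion
    # would really be an occurrence one position to the right)
    INF = max_errors + 1
    prev = [0] + [INF] * m
    best: tuple[int, int] | None = None

    def consider(err: int, alen: int) -> None:
        nonlocal best
        if err > max_errors:
            return
        if best is None or (err, -alen) < (best[0], -best[1]):
            best = (err, alen)

    for i in range(1, a + 1):
        cur = [INF] * (m + 1)
        cur[0] = min(i, INF)  # adapter bases deleted from the read
        lo = max(1, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            sub = prev[j - 1] + (
                0 if adapter[i - 1] == tail[j - 1] and tail[j - 1] != "N" else 1
            )
            ins = cur[j - 1] + 1
            dele = prev[j] + 1
            cur[j] = min(sub, ins, dele, INF)
        # prefix occurrence consuming the read to its 3' end
        if cur[m] <= max_errors:
            consider(cur[m], i)
        prev = cur
    # full-adapter internal occurrence: adapter fully consumed, read tail may continue
    full_best = min((v for v in prev[1:]), default=INF)
    if full_best <= max_errors:
        consider(full_best, a)
    return best


def trim_adapter(read: SequenceRead, settings: TrimSettings) -> TrimResult:
    """Trim the 3' adapter from one read.

    All occurrence start positions are scored; among qualifying occurrences
    (adapter match length >= ``min_adapter_len``, <= ``max_errors`` edits) the
    one with the fewest errors wins, ties going to the leftmost start.
    Preferring fewer errors over strict leftmost keeps a chance agreement of
    the insert's last base with the adapter's first base (a 1-error occurrence
    one position early) from eating into the insert when an exact occurrence
    follows.  A read whose remaining insert is shorter than ``min_read_len``
    is dropped ('too_short'); a read with no qualifying occurrence is returned
    unchanged and flagged 'no_adapter'.
    """
    if settings.skip_trimming or settings.adapter is None:
        return TrimResult("no_adapter", read)
    seq = read.sequence
    adapter = settings.adapter.upper().replace("U", "T")
    best: tuple[int, int] | None = None  # (errors, pos)
    for pos in range(0, len(seq)):
        if len(seq) - pos < settings.min_adapter_len - settings.max_errors:
            break
        hit = _match_errors(seq, pos, adapter, settings.max_errors)
        if hit is not None and hit[1] >= settings.min_adapter_len:
            if best is None or hit[0] < best[0]:
                best = (hit[0], pos)
            if best[0] == 0:
                break  # no occurrence can beat an exact one further right
    if best is None:
        return TrimResult("no_adapter", read)
    pos = best[1]
    if pos < settings.min_read_len:
        return TrimResult("too_short", None, adapter_start=pos)
    trimmed = SequenceRead(read.read_id, seq[:pos], read.qualities[:pos])
    return TrimResult("trimmed", trimmed, adapter_start=pos)


def trim_library(
    reads: Iterable[SequenceRead], settings: TrimSettings
) -> tuple[list[SequenceRead], dict[str, int]]:
    """Trim every read; returns (kept clean reads, status tallies)."""
    kept: list[SequenceRead] = []
    stats = Counter(trimmed=0, no_adapter=0, too_short=0)
    for read in reads:
        res = trim_adapter(read, settings)
        stats[res.status] += 1
        if res.read is not None:
            kept.append(res.read)
    return kept, dict(stats)


def detect_adapter(
    reads: Sequence[SequenceRead],
    k: int = 10,
    sample_size: int = 100000,
    min_fraction: float = 0.20,
) -> tuple[str, float] | None:
    """Infer the 3' adapter empirically from a read sample.

    Tallies all k-mers occurring in the 3' half of up to ``sample_size`` reads,
    seeds on the most frequent one (requiring it in >= ``min_fraction`` of
    sampled reads), then extends rightward base by base while >= 80% of the
    reads containing the candidate agree on the next base.  Returns the
    candidate and the fraction of sampled reads containing it, or None when no
    k-mer reaches the floor.
    """
    sample = [r.sequence for r in reads[:sample_size] if len(r.sequence) >= k]
    if not sample:
        return None
    tally: Counter[str] = Counter()
    for seq in sample:
        half = len(seq) // 2
        region = seq[half:]
        seen = {region[i : i + k] for i in range(0, len(region) - k + 1)}
        seen.discard("")
        tally.update(kmer for kmer in seen if "N" not in kmer)
    if not tally:
        return None
    seed, n_support = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
    if n_support < min_fraction * len(sample):
        return None
    candidate = seed
    for direction in (+1, -1):  # extend rightward, then leftward to the adapter start
        while True:
            votes: Counter[str] = Counter()
            n_holders = 0
            for seq in sample:
                idx = seq.find(candidate)
                if idx == -1:
                    continue
                n_holders += 1
                probe = idx + len(candidate) if direction == 1 else idx - 1
                if 0 <= probe < len(seq):
                    votes[seq[probe]] += 1
            if not votes:
                break
            base, n_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if n_votes < 0.80 * n_holders:
                break
            candidate = candidate + base if direction == 1 else base + candidate
    fraction = sum(1 for seq in sample if candidate[:k] in seq) / len(sample)
    return candidate, fraction


def collapse(reads: Iterable[SequenceRead | str]) -> list[CollapsedRead]:
    """Collapse clean reads by exact sequence identity.

    One record per distinct sequence with its multiplicity; uid numbering is
    deterministic (descending count, ties by sequence lexicographic order) and
    encodes the count as "XXX-YYY".
    """
    tally: Counter[str] = Counter()
    for read in reads:
        tally[read if isinstance(read, str) else read.sequence] += 1
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(uid=f"{i + 1}-{count}", sequence=seq, count=count)
        for i, (seq, count) in enumerate(ordered)
    ]
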