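"""Arm-switching detection across treatments.

A hairpin expressing mature miRNAs from both arms (5p and 3p) has a dominant
arm in a library when one arm's count exceeds the other by more than a
fold-change threshold (default 2) AND an absolute difference threshold
(default 10); otherwise no arm is dominant.  A treatment's arm is defined only
when every replicate agrees on the same non-none dominant arm, and an
arm-switch is called when at least two treatments have defined arms that
differ.  Raw (unnormalized) counts are compared; see the methods note for the
library-size caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass(frozen=True)
class ArmPair:
    hairpin_id: str
    mature5p_id: str
    mature3p_id: str


@dataclass(frozen=True)
class DominanceCall:
    library: str
    dominant: str  # '5p' | '3p' | 'none'
    c5: int
    c3: int


@dataclass(frozen=True)
class ArmSwitchCall:
    hairpin_id: str
    treatment_forms: tuple[tuple[str, str], ...]  # (treatment, '5p'|'3p') for defined treatments
    dominance: tuple[DominanceCall, ...]

    @property
    def switching_treatments(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.treatment_forms)


def dominant_form(
    c5: int | float, c3: int | float, fold_threshold: float = 2, diff_threshold: float = 10
) -> str:
    """Dominant arm for one library: '5p', '3p', or 'none'.

    An arm dominates when count_fold > fold_threshold (with a zero denominator
    the fold criterion is satisfied whenever the numerator is positive) and
    count difference > diff_threshold; both inequalities are strict.
    """
    if c5 < 0 or c3 < 0:
        raise ValueError("arm counts must be non-negative")
    if (c3 == 0 and c5 > 0 or c3 > 0 and c5 / c3 > fold_threshold) and c5 - c3 > diff_threshold:
        return "5p"
    if (c5 == 0 and c3 > 0 or c5 > 0 and c3 / c5 > fold_threshold) and c3 - c5 > diff_threshold:
        return "3p"
    return "none"


def arm_pairs(loci: Sequence) -> list[ArmPair]:
    """Hairpins carrying exactly one annotated 5p and one annotated 3p mature.

    Accepts :class:`~mirvar.hairpin_align.MatureLocus` records; hairpins with a
    single annotated arm (or duplicate arms) are skipped.
    """
    by_hairpin: dict[str, dict[str, list[str]]] = {}
    for locus in loci:
        by_hairpin.setdefault(locus.hairpin_id, {}).setdefault(locus.arm, []).append(
            locus.mature_id
        )
    pairs = []
    for hairpin_id in sorted(by_hairpin):
        arms = by_hairpin[hairpin_id]
        if len(arms.get("5p", ())) == 1 and len(arms.get("3p", ())) == 1:
            pairs.append(ArmPair(hairpin_id, arms["5p"][0], arms["3p"][0]))
    return pairs


def detect_switches(
    counts: Mapping[str, Mapping[str, int]],
    design: Mapping[str, str],
    pairs: Sequence[ArmPair],
    fold_threshold: float = 2,
    diff_threshold: float = 10,
) -> list[ArmSwitchCall]:
    """Arm-switch calls from a mature x library count table and a design map.

    ``counts`` maps mature id -> {library: integer count}; ``design`` maps
    library -> treatment and must name at least two treatments.  A call is
    emitted for a hairpin when >= 2 treatments have defined (replicate-
    consistent, non-none) dominant arms that are not all identical; the call
    lists exactly the treatments with defined arms.
    """
    treatments: dict[str, list[str]] = {}
    for lib, treat in design.items():
        treatments.setdefault(treat, []).append(lib)
    if len(treatments) < 2:
        raise ValueError("arm-switch detection needs >= 2 treatments")
    for pair in pairs:
        for mature_id in (pair.mature5p_id, pair.mature3p_id):
            row = counts.get(mature_id)
            if row is None:
                continue
            for lib in design:
                if lib not in row:
                    raise ValueError(f"design library {lib!r} absent from the count table")
    calls: list[ArmSwitchCall] = []
    for pair in pairs:
        row5 = counts.get(pair.mature5p_id, {})
        row3 = counts.get(pair.mature3p_id, {})
        dominance: list[DominanceCall] = []
        treatment_forms: list[tuple[str, str]] = []
        for treat in sorted(treatments):
            forms = set()
            for lib in sorted(treatments[treat]):
                c5 = row5.get(lib, 0)
                c3 = row3.get(lib, 0)
                form = dominant_form(c5, c3, fold_threshold, diff_threshold)
                dominance.append(DominanceCall(lib, form, c5, c3))
                forms.add(form)
            if len(forms) == 1 and forms != {"none"}:
                treatment_forms.append((treat, forms.pop()))
        defined = {form for _, form in treatment_forms}
        if len(treatment_forms) >= 2 and len(defined) > 1:
            calls.append(
                ArmSwitchCall(
                    hairpin_id=pair.hairpin_id,
                    treatment_forms=tuple(treatment_forms),
                    dominance=tuple(dominance),
                )
            )
    return calls
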