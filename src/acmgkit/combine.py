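"""Criterion combination: tallying, suppression, and the five-tier verdict.

This is the procedural classifier. Its arithmetic is written
independently of the declarative clause table in :mod:`acmgkit.table1`;
an exhaustive cross-check of the two over every tally with buckets in
0..4 is part of the test suite and of the ``audit-rules`` command.

Two laboratory behaviors live here rather than in the verdict rules:

* **Benign clamping** — benign criteria arriving at Moderate or
  VeryStrong are reset to their default strength before counting.
* **BS suppression** — if exactly one Strong benign criterion (BS1–BS4)
  is present together with at least one pathogenic criterion of any
  strength, that BS criterion is not considered in deciding the final
  verdict. With two or more BS criteria the rule does not apply and
  contradictory evidence resolves to UncertainSignificance.
"""

from __future__ import annotations

from .model import (
    ClassificationResult,
    CriterionAssignment,
    CriterionCode,
    StrengthLevel,
    StrengthTally,
    Verdict,
    clamp_benign_strength,
)
from .table1 import classify_declarative

BS_CODES = frozenset(
    {CriterionCode.BS1, CriterionCode.BS2, CriterionCode.BS3, CriterionCode.BS4}
)


def tally(assignments: list[CriterionAssignment]) -> StrengthTally:
    """Count active assignments into effective-strength buckets.

    Applies benign clamping, then the single-BS suppression rule.
    Rejects duplicate active codes. Assignments already marked
    suppressed are ignored.
    """
    active: list[CriterionAssignment] = []
    seen: set[CriterionCode] = set()
    for a in assignments:
        if a.suppressed:
            continue
        if a.code in seen:
            raise ValueError(f"duplicate criterion in input: {a.code.value}")
        seen.add(a.code)
        if a.code.is_benign:
            a = clamp_benign_strength(a)
        active.append(a)

    n_pathogenic = sum(1 for a in active if a.code.is_pathogenic)
    bs_active = [a for a in active if a.code in BS_CODES]
    suppressed: set[CriterionCode] = set()
    if len(bs_active) == 1 and n_pathogenic >= 1:
        suppressed = {bs_active[0].code}

    t = StrengthTally(suppressed_codes=suppressed)
    for a in active:
        if a.code in suppressed:
            continue
        if a.code.is_pathogenic:
            if a.strength is StrengthLevel.VERY_STRONG:
                t.n_pvs += 1
            elif a.strength is StrengthLevel.STRONG:
                t.n_ps += 1
            elif a.strength is StrengthLevel.MODERATE:
                t.n_pm += 1
            else:
                t.n_pp += 1
        else:
            if a.strength is StrengthLevel.STAND_ALONE:
                t.n_ba += 1
            elif a.strength is StrengthLevel.STRONG:
                t.n_bs += 1
            else:
                t.n_bp += 1
    return t


def classify(t: StrengthTally) -> Verdict:
    """Five-tier verdict from a strength tally (procedural form)."""
    pathogenic = (
        t.n_pvs >= 2
        or (
            t.n_pvs >= 1
            and (
                t.n_ps >= 1
                or t.n_pm >= 2
                or (t.n_pm >= 1 and t.n_pp >= 1)
                or t.n_pp >= 2
            )
        )
        or t.n_ps >= 2
        or (
            t.n_ps == 1
            and (
                t.n_pm >= 3
                or (t.n_pm == 2 and t.n_pp >= 2)
                or (t.n_pm == 1 and t.n_pp >= 4)
            )
        )
    )
    likely_pathogenic = not pathogenic and (
        (t.n_pvs == 1 and t.n_pm == 1)
        or (t.n_ps == 1 and 1 <= t.n_pm <= 2)
        or (t.n_ps == 1 and t.n_pp >= 2)
        or t.n_pm >= 3
        or (t.n_pm == 2 and t.n_pp >= 2)
        or (t.n_pm == 1 and t.n_pp >= 3)
    )
    benign = t.n_ba >= 1 or t.n_bs >= 2
    likely_benign = not benign and (t.n_bs == 1 or t.n_bp >= 2)

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return Verdict.UNCERTAIN
    if pathogenic:
        return Verdict.PATHOGENIC
    if likely_pathogenic:
        return Verdict.LIKELY_PATHOGENIC
    if benign:
        return Verdict.BENIGN
    if likely_benign:
        return Verdict.LIKELY_BENIGN
    return Verdict.UNCERTAIN


def classify_with_audit(
    assignments: list[CriterionAssignment], variant_id: str = ""
) -> ClassificationResult:
    """Full classification with audit trail.

    Returns the verdict, the tally, every suppressed/clamped criterion
    with its reason, and the matched clause identifier from the
    declarative table (consistency of the two classifiers is enforced
    by the exhaustive cross-check in the test suite).
    """
    audit: list[str] = []
    recorded: list[CriterionAssignment] = []
    for a in assignments:
        if a.code.is_benign and not a.suppressed:
            clamped = clamp_benign_strength(a)
            if clamped.strength is not a.strength:
                audit.append(
                    f"{a.code.value}: strength {a.strength.label()} clamped to "
                    f"{clamped.strength.label()}"
                )
            a = clamped
        recorded.append(a)

    t = tally(recorded)
    for code in sorted(t.suppressed_codes, key=lambda c: c.value):
        audit.append(
            f"{code.value}: single Strong benign criterion suppressed in the "
            "presence of pathogenic evidence"
        )
    recorded = [
        a.model_copy(update={"suppressed": True}) if a.code in t.suppressed_codes else a
        for a in recorded
    ]

    verdict = classify(t)
    _, clause = classify_declarative(t)
    return ClassificationResult(
        variant_id=variant_id,
        assignments=recorded,
        tally=t,
        verdict=verdict,
        matched_clause=clause,
        audit=audit,
    )
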