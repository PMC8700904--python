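"""Declarative transcription of the criterion-combination table.

Each clause is a literal transcription of one line of the laboratory's
modified ACMG/AMP combination table: a tier, a clause identifier, and
minimum/exact bucket requirements on the strength tally. The verdict is
derived by evaluating clauses in order; if both a pathogenic-side and a
benign-side clause match, the evidence is contradictory and the verdict
is UncertainSignificance.

Laboratory modifications relative to the 2015 guideline table:
  * Pathogenic (i)(c): 1 VeryStrong + 1 Moderate + ≥1 Supporting
    (the guideline requires ≥2 Supporting here);
  * Pathogenic (i)(e): a second VeryStrong criterion suffices;
  * Likely Pathogenic (vi): 1 Moderate + ≥3 Supporting
    (the guideline requires ≥4).

This module is deliberately data-driven and independent of the
procedural classifier in :mod:`acmgkit.combine`; the two are checked
against each other exhaustively.
"""

from __future__ import annotations

from typing import Callable

from .model import StrengthTally, Verdict

Clause = tuple[str, Verdict, Callable[[StrengthTally], bool]]

PATHOGENIC_CLAUSES: list[Clause] = [
    (
        "Pathogenic(i.a)",
        Verdict.PATHOGENIC,
        lambda t: t.n_pvs >= 1 and t.n_ps >= 1,
    ),
    (
        "Pathogenic(i.b)",
        Verdict.PATHOGENIC,
        lambda t: t.n_pvs >= 1 and t.n_pm >= 2,
    ),
    (
        "Pathogenic(i.c)",
        Verdict.PATHOGENIC,
        lambda t: t.n_pvs >= 1 and t.n_pm == 1 and t.n_pp >= 1,
    ),
    (
        "Pathogenic(i.d)",
        Verdict.PATHOGENIC,
        lambda t: t.n_pvs >= 1 and t.n_pp >= 2,
    ),
    (
        "Pathogenic(i.e)",
        Verdict.PATHOGENIC,
        lambda t: t.n_pvs >= 2,
    ),
    (
        "Pathogenic(ii)",
        Verdict.PATHOGENIC,
        lambda t: t.n_ps >= 2,
    ),
    (
        "Pathogenic(iii.a)",
        Verdict.PATHOGENIC,
        lambda t: t.n_ps == 1 and t.n_pm >= 3,
    ),
    (
        "Pathogenic(iii.b)",
        Verdict.PATHOGENIC,
        lambda t: t.n_ps == 1 and t.n_pm == 2 and t.n_pp >= 2,
    ),
    (
        "Pathogenic(iii.c)",
        Verdict.PATHOGENIC,
        lambda t: t.n_ps == 1 and t.n_pm == 1 and t.n_pp >= 4,
    ),
]

LIKELY_PATHOGENIC_CLAUSES: list[Clause] = [
    (
        "LikelyPathogenic(i)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_pvs == 1 and t.n_pm == 1,
    ),
    (
        "LikelyPathogenic(ii)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_ps == 1 and 1 <= t.n_pm <= 2,
    ),
    (
        "LikelyPathogenic(iii)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_ps == 1 and t.n_pp >= 2,
    ),
    (
        "LikelyPathogenic(iv)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_pm >= 3,
    ),
    (
        "LikelyPathogenic(v)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_pm == 2 and t.n_pp >= 2,
    ),
    (
        "LikelyPathogenic(vi)",
        Verdict.LIKELY_PATHOGENIC,
        lambda t: t.n_pm == 1 and t.n_pp >= 3,
    ),
]

BENIGN_CLAUSES: list[Clause] = [
    ("Benign(i)", Verdict.BENIGN, lambda t: t.n_ba >= 1),
    ("Benign(ii)", Verdict.BENIGN, lambda t: t.n_bs >= 2),
]

LIKELY_BENIGN_CLAUSES: list[Clause] = [
    ("LikelyBenign(i)", Verdict.LIKELY_BENIGN, lambda t: t.n_bs == 1),
    ("LikelyBenign(ii)", Verdict.LIKELY_BENIGN, lambda t: t.n_bp >= 2),
]

ALL_CLAUSES: list[Clause] = (
    PATHOGENIC_CLAUSES
    + LIKELY_PATHOGENIC_CLAUSES
    + BENIGN_CLAUSES
    + LIKELY_BENIGN_CLAUSES
)


def match_clauses(tally: StrengthTally) -> list[str]:
    """Identifiers of every clause the tally satisfies, in table order."""
    return [cid for cid, _, pred in ALL_CLAUSES if pred(tally)]


def classify_declarative(tally: StrengthTally) -> tuple[Verdict, str]:
    """Verdict by literal clause evaluation.

    The pathogenic side takes the strongest matched tier (Pathogenic
    over LikelyPathogenic) and the benign side likewise; if both sides
    match, the criteria are contradictory → UncertainSignificance.
    """
    path_hit = next(
        ((cid, v) for cid, v, pred in PATHOGENIC_CLAUSES if pred(tally)), None
    )
    if path_hit is None:
        path_hit = next(
            ((cid, v) for cid, v, pred in LIKELY_PATHOGENIC_CLAUSES if pred(tally)),
            None,
        )
    benign_hit = next(
        ((cid, v) for cid, v, pred in BENIGN_CLAUSES if pred(tally)), None
    )
    if benign_hit is None:
        benign_hit = next(
            ((cid, v) for cid, v, pred in LIKELY_BENIGN_CLAUSES if pred(tally)), None
        )
    if path_hit and benign_hit:
        return Verdict.UNCERTAIN, "UncertainSignificance(contradictory)"
    if path_hit:
        return path_hit[1], path_hit[0]
    if benign_hit:
        return benign_hit[1], benign_hit[0]
    return Verdict.UNCERTAIN, "UncertainSignificance(none)"
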