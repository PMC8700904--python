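"""Reviewer adjustments and the manual-criteria grading checklist.

Eleven criteria cannot be automated from database evidence alone
(BS3, BS4, BP2, BP5, PS2, PS3, PS4, PM3, PM6, PP1, PP4): they need
segregation data, functional studies, or laboratory case counts. The
molecular geneticist adds them — and re-grades or removes automatic
ones — as validated :class:`~acmgkit.model.Adjustment` records. Each
adjustment is checked against a :class:`ChecklistPolicy` giving the
allowed strength range per criterion; a batch is applied atomically
and the variant re-classified, with the original automatic assignments
kept as provenance.

The ``grade_*`` helpers encode the checklist's quantitative grading
rules for the manual criteria (e.g. co-segregation count breakpoints
for PP1).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .combine import classify_with_audit
from .model import (
    Adjustment,
    ClassificationResult,
    CriterionAssignment,
    CriterionCode,
    GeneContext,
    StrengthLevel,
    default_strength,
)

MANUAL_ONLY_CODES = frozenset(
    {
        CriterionCode.BS3,
        CriterionCode.BS4,
        CriterionCode.BP2,
        CriterionCode.BP5,
        CriterionCode.PS2,
        CriterionCode.PS3,
        CriterionCode.PS4,
        CriterionCode.PM3,
        CriterionCode.PM6,
        CriterionCode.PP1,
        CriterionCode.PP4,
    }
)

_P_FULL = {
    StrengthLevel.SUPPORTING,
    StrengthLevel.MODERATE,
    StrengthLevel.STRONG,
    StrengthLevel.VERY_STRONG,
}
_B_STD = {StrengthLevel.SUPPORTING, StrengthLevel.STRONG}


def _default_allowed() -> dict[CriterionCode, set[StrengthLevel]]:
    """Per-criterion strength ranges from the checklist.

    Pathogenic criteria may in general be moved anywhere from
    Supporting to VeryStrong; the checklist narrows some (PM1 only
    Moderate/Supporting, PS1 Strong or Supporting, PM3 and PP1 up to
    Strong, PP4 up to Moderate). Benign criteria never take Moderate or
    VeryStrong; BA1 is stand-alone only, and BS1 may reach StandAlone
    for high-penetrance dominant disease (gene-context gated).
    """
    allowed: dict[CriterionCode, set[StrengthLevel]] = {}
    for code in CriterionCode:
        if code is CriterionCode.BA1:
            allowed[code] = {StrengthLevel.STAND_ALONE}
        elif code is CriterionCode.BS1:
            allowed[code] = _B_STD | {StrengthLevel.STAND_ALONE}
        elif code.is_benign:
            allowed[code] = set(_B_STD)
        else:
            allowed[code] = set(_P_FULL)
    allowed[CriterionCode.PM1] = {StrengthLevel.MODERATE, StrengthLevel.SUPPORTING}
    allowed[CriterionCode.PS1] = {StrengthLevel.STRONG, StrengthLevel.SUPPORTING}
    allowed[CriterionCode.PM3] = {
        StrengthLevel.SUPPORTING,
        StrengthLevel.MODERATE,
        StrengthLevel.STRONG,
    }
    allowed[CriterionCode.PM6] = {
        StrengthLevel.SUPPORTING,
        StrengthLevel.MODERATE,
        StrengthLevel.STRONG,
    }
    allowed[CriterionCode.PP1] = {
        StrengthLevel.SUPPORTING,
        StrengthLevel.MODERATE,
        StrengthLevel.STRONG,
    }
    allowed[CriterionCode.PP4] = {StrengthLevel.SUPPORTING, StrengthLevel.MODERATE}
    return allowed


class ChecklistPolicy(BaseModel):
    allowed_strengths: dict[CriterionCode, set[StrengthLevel]] = Field(
        default_factory=_default_allowed
    )
    manual_only_codes: frozenset[CriterionCode] = MANUAL_ONLY_CODES

    @model_validator(mode="after")
    def _check(self) -> "ChecklistPolicy":
        for code, strengths in self.allowed_strengths.items():
            for s in strengths:
                if code.is_benign and s in (
                    StrengthLevel.MODERATE,
                    StrengthLevel.VERY_STRONG,
                ):
                    raise ValueError(
                        f"policy allows benign {code.value} at {s.label()}"
                    )
                if code.is_pathogenic and s is StrengthLevel.STAND_ALONE:
                    raise ValueError(
                        f"policy allows pathogenic {code.value} at StandAlone"
                    )
        return self


class AdjustmentError(ValueError):
    """Raised when a reviewer adjustment (or batch) fails validation."""


def validate_adjustment(
    adj: Adjustment,
    policy: Optional[ChecklistPolicy] = None,
    gene_context: Optional[GeneContext] = None,
) -> tuple[bool, str]:
    """Check one adjustment against the checklist policy.

    Returns (ok, reason). BS1 at StandAlone additionally requires the
    gene context's high-penetrance flag.
    """
    policy = policy or ChecklistPolicy()
    if adj.code not in policy.allowed_strengths:
        return False, f"unknown criterion code {adj.code!r}"
    if adj.action == "remove":
        return True, "removal always permitted with justification"
    target = adj.new_strength if adj.new_strength is not None else default_strength(adj.code)
    if target not in policy.allowed_strengths[adj.code]:
        return (
            False,
            f"{adj.code.value} may not be set to {target.label()} "
            f"(allowed: {sorted(s.label() for s in policy.allowed_strengths[adj.code])})",
        )
    if (
        adj.code is CriterionCode.BS1
        and target is StrengthLevel.STAND_ALONE
        and not (gene_context is not None and gene_context.high_penetrance)
    ):
        return (
            False,
            "BS1 stand-alone requires a high-penetrance dominant gene context",
        )
    return True, "within checklist range"


def grade_pp1(n_affected: int) -> StrengthLevel:
    """Co-segregation strength from the number of affected carriers
    (including the tested individual): ≥4 Strong, 2–3 Moderate,
    1 Supporting."""
    if n_affected < 1:
        raise ValueError("n_affected must be >= 1 (includes the tested individual)")
    if n_affected >= 4:
        return StrengthLevel.STRONG
    if n_affected >= 2:
        return StrengthLevel.MODERATE
    return StrengthLevel.SUPPORTING


def grade_pm3(
    n_trans_pathogenic: int, homozygous: bool = False, multiple_individuals: bool = False
) -> Optional[StrengthLevel]:
    """In-trans evidence for recessive disorders.

    None without any trans observation or homozygosity; Strong with
    multiple different pathogenic partners or multiple affected
    individuals; Supporting for a single trans observation or a
    homozygous genotype; Moderate otherwise (the guideline default).
    """
    if n_trans_pathogenic < 0:
        raise ValueError("n_trans_pathogenic must be >= 0")
    if n_trans_pathogenic == 0 and not homozygous:
        return None
    if n_trans_pathogenic >= 2 or multiple_individuals:
        return StrengthLevel.STRONG
    if n_trans_pathogenic == 1 or homozygous:
        return StrengthLevel.SUPPORTING
    return StrengthLevel.MODERATE


def grade_pp4(phenotype_gene_count: int, single_gene: bool = False) -> Optional[StrengthLevel]:
    """Phenotype specificity: Moderate for true single-gene disorders,
    Supporting when no more than 5 genes cause the phenotype."""
    if phenotype_gene_count < 1:
        raise ValueError("phenotype_gene_count must be >= 1")
    if single_gene:
        return StrengthLevel.MODERATE
    if phenotype_gene_count <= 5:
        return StrengthLevel.SUPPORTING
    return None


def grade_ps4(
    n_unrelated_affected: int, has_case_control: bool = False
) -> Optional[StrengthLevel]:
    """Case prevalence: Strong with case/control data or ≥5 unrelated
    affected individuals observed in the laboratory."""
    if n_unrelated_affected < 0:
        raise ValueError("n_unrelated_affected must be >= 0")
    if has_case_control or n_unrelated_affected >= 5:
        return StrengthLevel.STRONG
    return None


def apply_adjustments(
    result: ClassificationResult,
    adjustments: list[Adjustment],
    policy: Optional[ChecklistPolicy] = None,
    gene_context: Optional[GeneContext] = None,
) -> ClassificationResult:
    """Apply a batch of reviewer adjustments and re-classify.

    The batch is atomic: any invalid adjustment rejects the whole batch
    and the input result is returned unchanged semantics-wise (the
    function raises; callers keep the original object). The audit trail
    records each adjustment with its justification, and the original
    automatic verdict is preserved on the returned result.
    """
    policy = policy or ChecklistPolicy()
    working: dict[CriterionCode, CriterionAssignment] = {
        a.code: a for a in result.assignments if not a.suppressed
    }
    audit = list(result.audit)

    # validate everything against the evolving state before mutating
    staged = {c: a for c, a in working.items()}
    for adj in adjustments:
        ok, reason = validate_adjustment(adj, policy, gene_context)
        if not ok:
            raise AdjustmentError(f"{adj.code.value} {adj.action}: {reason}")
        if adj.action == "add" and adj.code in staged:
            raise AdjustmentError(
                f"{adj.code.value} add: already active; use set_strength"
            )
        if adj.action in ("remove", "set_strength") and adj.code not in staged:
            raise AdjustmentError(f"{adj.code.value} {adj.action}: criterion not active")
        if adj.action == "add":
            staged[adj.code] = CriterionAssignment(
                code=adj.code,
                strength=adj.new_strength or default_strength(adj.code),
                source="manual",
            )
        elif adj.action == "remove":
            del staged[adj.code]
        else:
            staged[adj.code] = staged[adj.code].model_copy(
                update={"strength": adj.new_strength}
            )

    final: list[CriterionAssignment] = []
    for adj in adjustments:
        audit.append(
            f"reviewer {adj.action} {adj.code.value}"
            + (f" -> {adj.new_strength.label()}" if adj.new_strength else "")
            + f": {adj.justification}"
        )
    for code, a in staged.items():
        if code in working and a is working[code]:
            final.append(a)
        elif code in working:
            final.append(
                a.model_copy(update={"source": "manual", "rationale": a.rationale})
            )
        else:
            final.append(a)

    reclassified = classify_with_audit(final, variant_id=result.variant_id)
    return reclassified.model_copy(
        update={
            "excluded": result.excluded,
            "decision_maf": result.decision_maf,
            "auto_verdict": result.auto_verdict or result.verdict,
            "adjustments_applied": list(result.adjustments_applied) + list(adjustments),
            "audit": audit + reclassified.audit,
            "phenotype_modifier": result.phenotype_modifier,
        }
    )
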