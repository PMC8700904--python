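"""Shared domain types for ACMG/AMP sequence-variant classification.

The ACMG/AMP framework scores a variant against 28 evidence criteria —
16 pathogenic (PVS1, PS1–PS4, PM1–PM6, PP1–PP5) and 12 benign (BA1,
BS1–BS4, BP1–BP7) — each carrying a default evidence strength that a
curator may re-grade. This module defines the criterion vocabulary, the
ordered strength scale, the per-variant evidence containers consumed by
the automatic assignment engine, and the classification result object.

All containers are pydantic models: they validate on construction and
round-trip losslessly through JSON / tabular serialization.
"""

from __future__ import annotations

import enum
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class CriterionCode(str, enum.Enum):
    """The 28 ACMG/AMP evidence criterion codes."""

    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"

    @property
    def is_pathogenic(self) -> bool:
        return self.value.startswith("P")

    @property
    def is_benign(self) -> bool:
        return self.value.startswith("B")


PATHOGENIC_CODES = frozenset(c for c in CriterionCode if c.is_pathogenic)
BENIGN_CODES = frozenset(c for c in CriterionCode if c.is_benign)


class StrengthLevel(enum.IntEnum):
    """Ordered evidence-strength scale.

    StandAlone sits above VeryStrong for comparison purposes only; it is
    assignable solely to benign criteria (BA1 alone decides Benign).
    Benign criteria never take Moderate or VeryStrong.
    """

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5

    def label(self) -> str:
        return _STRENGTH_LABELS[self]


_STRENGTH_LABELS = {
    StrengthLevel.SUPPORTING: "Supporting",
    StrengthLevel.MODERATE: "Moderate",
    StrengthLevel.STRONG: "Strong",
    StrengthLevel.VERY_STRONG: "VeryStrong",
    StrengthLevel.STAND_ALONE: "StandAlone",
}
_STRENGTH_BY_LABEL = {v: k for k, v in _STRENGTH_LABELS.items()}


def strength_from_label(label: str) -> StrengthLevel:
    try:
        return _STRENGTH_BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown strength level: {label!r}") from None


PATHOGENIC_STRENGTHS = frozenset(
    {
        StrengthLevel.SUPPORTING,
        StrengthLevel.MODERATE,
        StrengthLevel.STRONG,
        StrengthLevel.VERY_STRONG,
    }
)
BENIGN_STRENGTHS = frozenset(
    {StrengthLevel.SUPPORTING, StrengthLevel.STRONG, StrengthLevel.STAND_ALONE}
)


def default_strength(code: CriterionCode) -> StrengthLevel:
    """Canonical default strength of an ACMG criterion.

    PVS1→VeryStrong, PS*→Strong, PM*→Moderate, PP*→Supporting,
    BA1→StandAlone, BS*→Strong, BP*→Supporting.
    """
    if not isinstance(code, CriterionCode):
        try:
            code = CriterionCode(str(code))
        except ValueError:
            raise ValueError(f"unknown criterion code: {code!r}") from None
    prefix = code.value[:2]
    if code is CriterionCode.PVS1:
        return StrengthLevel.VERY_STRONG
    if code is CriterionCode.BA1:
        return StrengthLevel.STAND_ALONE
    return {
        "PS": StrengthLevel.STRONG,
        "PM": StrengthLevel.MODERATE,
        "PP": StrengthLevel.SUPPORTING,
        "BS": StrengthLevel.STRONG,
        "BP": StrengthLevel.SUPPORTING,
    }[prefix]


class Verdict(str, enum.Enum):
    """Five-tier clinical classification."""

    BENIGN = "Benign"
    LIKELY_BENIGN = "LikelyBenign"
    UNCERTAIN = "UncertainSignificance"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    PATHOGENIC = "Pathogenic"

    @property
    def rank(self) -> int:
        """Position on the benign→pathogenic axis (0..4)."""
        return _VERDICT_RANK[self]


_VERDICT_RANK = {
    Verdict.BENIGN: 0,
    Verdict.LIKELY_BENIGN: 1,
    Verdict.UNCERTAIN: 2,
    Verdict.LIKELY_PATHOGENIC: 3,
    Verdict.PATHOGENIC: 4,
}


class CriterionAssignment(BaseModel):
    """One criterion with its effective strength and provenance.

    ``source`` records who set it: the automatic engine (``auto``), a
    reviewer (``manual``), or an upstream annotator whose calls arrive
    pre-computed with the evidence (``external``). Suppressed
    assignments never contribute to verdict counting.
    """

    code: CriterionCode
    strength: StrengthLevel
    source: Literal["auto", "manual", "external"] = "auto"
    suppressed: bool = False
    rationale: str = ""
    downgrade_suggested: bool = False

    @model_validator(mode="after")
    def _check_polarity(self) -> "CriterionAssignment":
        # Pathogenic criteria can never reach StandAlone. A benign
        # criterion at Moderate/VeryStrong is representable — it is the
        # raw state an upstream annotator may deliver (e.g. BP6 boosted
        # by ClinVar evidence) — but clamp_benign_strength resets it
        # before any counting.
        if self.code.is_pathogenic and self.strength not in PATHOGENIC_STRENGTHS:
            raise ValueError(
                f"{self.code.value}: pathogenic criteria cannot take "
                f"{self.strength.label()}"
            )
        if self.code.is_benign and self.strength is StrengthLevel.VERY_STRONG:
            # representable only transiently; StandAlone is BA1-only
            pass
        if (
            self.code.is_benign
            and self.strength is StrengthLevel.STAND_ALONE
            and self.code is not CriterionCode.BA1
        ):
            # BS1 may be used stand-alone for high-penetrance AD disease;
            # other benign codes never reach StandAlone.
            if self.code is not CriterionCode.BS1:
                raise ValueError(
                    f"{self.code.value}: StandAlone is restricted to BA1/BS1"
                )
        return self


def clamp_benign_strength(assignment: CriterionAssignment) -> CriterionAssignment:
    """Clamp a benign criterion back to its standard strength.

    Benign criteria are never counted at Moderate or VeryStrong; a call
    boosted to either is reset to the code's default (Supporting or
    Strong). Idempotent. Rejects pathogenic-polarity input.
    """
    if assignment.code.is_pathogenic:
        raise ValueError(
            f"clamp_benign_strength: {assignment.code.value} has pathogenic polarity"
        )
    if assignment.strength not in (StrengthLevel.MODERATE, StrengthLevel.VERY_STRONG):
        return assignment
    target = default_strength(assignment.code)
    note = (assignment.rationale + "; " if assignment.rationale else "") + (
        f"strength {assignment.strength.label()} clamped to default {target.label()}"
    )
    return assignment.model_copy(update={"strength": target, "rationale": note})


class GeneContext(BaseModel):
    """Per-gene disease context used by inheritance-aware rules."""

    gene: str = ""
    inheritance: set[Literal["AD", "AR", "XL"]] = Field(default_factory=set)
    late_onset: bool = False  # disables BS2
    phenotype_gene_count: int = Field(default=0, ge=0)
    single_gene_disorder: bool = False
    lof_mechanism: bool = False
    high_penetrance: bool = False
    # gene-level missense statistics flags (PP2 / BP1); mutually exclusive
    low_benign_missense_rate: bool = False
    truncating_mechanism: bool = False

    @model_validator(mode="after")
    def _check(self) -> "GeneContext":
        if self.single_gene_disorder and self.phenotype_gene_count != 1:
            raise ValueError("single_gene_disorder implies phenotype_gene_count == 1")
        if self.low_benign_missense_rate and self.truncating_mechanism:
            raise ValueError(
                "PP2 and BP1 gene flags are mutually exclusive "
                "(missense-constrained vs truncating-mechanism)"
            )
        return self


DEFAULT_EXCLUDED_SUBPOPS = frozenset({"FIN", "ASJ", "OTH"})


class PopulationRecord(BaseModel):
    """gnomAD-style population counts and subpopulation frequencies."""

    subpop_frequencies: dict[str, float] = Field(default_factory=dict)
    excluded_subpops: set[str] = Field(
        default_factory=lambda: set(DEFAULT_EXCLUDED_SUBPOPS)
    )
    allele_count: int = Field(default=0, ge=0)
    homozygote_count: int = Field(default=0, ge=0)
    hemizygote_count: int = Field(default=0, ge=0)

    @field_validator("subpop_frequencies")
    @classmethod
    def _check_freqs(cls, v: dict[str, float]) -> dict[str, float]:
        for name, f in v.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"subpopulation {name!r}: frequency {f} not in [0,1]")
        return v


class PredictorPanel(BaseModel):
    """In-silico predictor calls plus dbscSNV-style splice scores."""

    n_pathogenic_calls: int = Field(default=0, ge=0)
    n_benign_calls: int = Field(default=0, ge=0)
    ada_score: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    rf_score: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @property
    def total_calls(self) -> int:
        return self.n_pathogenic_calls + self.n_benign_calls


class DomainContext(BaseModel):
    """Protein-domain and mutational-hotspot statistics around the variant.

    ``pathogenic_neighbor_distances_nt`` lists, for each pathogenic
    missense/in-frame neighbor, its coding-sequence distance (nt) from
    the variant of interest.
    """

    in_domain: bool = False
    domain_name: str = ""
    domain_length_aa: int = Field(default=1, ge=1)
    n_pathogenic_in_domain: int = Field(default=0, ge=0)
    n_benign_in_domain: int = Field(default=0, ge=0)
    is_disulfide_bond_annotation: bool = False
    variant_at_bond_residue: bool = False
    pathogenic_neighbor_distances_nt: list[int] = Field(default_factory=list)

    @field_validator("pathogenic_neighbor_distances_nt")
    @classmethod
    def _check_distances(cls, v: list[int]) -> list[int]:
        if any(d < 0 for d in v):
            raise ValueError("neighbor distances must be >= 0")
        return v


Consequence = Literal[
    "missense",
    "nonsense",
    "frameshift",
    "canonical_splice",
    "intronic",
    "synonymous",
    "inframe_indel",
    "stop_loss",
    "initiation_codon",
    "other",
]


class TranscriptContext(BaseModel):
    """Transcript-level consequence and positional flags."""

    consequence: Consequence = "other"
    at_exon_first_or_last_base: bool = False
    in_last_exon_or_last50bp_penultimate: bool = False
    downstream_plp_variants: bool = False
    in_repeat_region_no_function: bool = False
    same_aa_change_as_pathogenic: bool = False
    alt_variant_at_residue_classification: Literal[
        "pathogenic", "likely_pathogenic", "none"
    ] = "none"
    pm5_dubious: bool = False


class ClinicalDbContext(BaseModel):
    """ClinVar-style interpretation summary for the variant."""

    clinvar_review_stars: int = Field(default=0, ge=0, le=4)
    clinvar_interpretation: Literal["pathogenic", "benign", "conflicting", "none"] = (
        "none"
    )
    other_db_submissions: bool = False


class EvidenceBundle(BaseModel):
    """All pre-annotated facts about one variant.

    Absent evidence defaults to "no criterion triggered", never to an
    error — real annotation is sparse. ``variant_id`` is an opaque
    HGVS-style label; no parsing is performed.
    """

    variant_id: str = Field(min_length=1)
    gene_context: GeneContext = Field(default_factory=GeneContext)
    population: PopulationRecord = Field(default_factory=PopulationRecord)
    predictors: PredictorPanel = Field(default_factory=PredictorPanel)
    domain: DomainContext = Field(default_factory=DomainContext)
    transcript: TranscriptContext = Field(default_factory=TranscriptContext)
    clinical_db: ClinicalDbContext = Field(default_factory=ClinicalDbContext)
    externally_supplied_criteria: list[CriterionAssignment] = Field(
        default_factory=list
    )


class ReportTier(str, enum.Enum):
    PRIMARY = "Primary"
    SECONDARY = "Secondary"
    NOT_REPORTED = "NotReported"


class StrengthTally(BaseModel):
    """Counts of active criteria per effective-strength bucket.

    Each active assignment contributes to exactly one bucket determined
    by its effective strength (PVS1 downgraded to Moderate counts in
    ``n_pm``).
    """

    n_pvs: int = Field(default=0, ge=0)
    n_ps: int = Field(default=0, ge=0)
    n_pm: int = Field(default=0, ge=0)
    n_pp: int = Field(default=0, ge=0)
    n_ba: int = Field(default=0, ge=0)
    n_bs: int = Field(default=0, ge=0)
    n_bp: int = Field(default=0, ge=0)
    suppressed_codes: set[CriterionCode] = Field(default_factory=set)


class Adjustment(BaseModel):
    """A reviewer action: add, remove, or re-grade one criterion."""

    code: CriterionCode
    action: Literal["add", "remove", "set_strength"]
    new_strength: Optional[StrengthLevel] = None
    justification: str = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "Adjustment":
        if self.action == "set_strength" and self.new_strength is None:
            raise ValueError("set_strength requires new_strength")
        return self


class ClassificationResult(BaseModel):
    """Verdict plus full audit trail for one variant."""

    variant_id: str = ""
    assignments: list[CriterionAssignment] = Field(default_factory=list)
    excluded: list[tuple[CriterionCode, str]] = Field(default_factory=list)
    tally: StrengthTally = Field(default_factory=StrengthTally)
    verdict: Verdict = Verdict.UNCERTAIN
    matched_clause: str = ""
    decision_maf: float = 0.0
    report_tier: Optional[ReportTier] = None
    phenotype_modifier: bool = False
    auto_verdict: Optional[Verdict] = None
    adjustments_applied: list[Adjustment] = Field(default_factory=list)
    audit: list[str] = Field(default_factory=list)

    @property
    def active_assignments(self) -> list[CriterionAssignment]:
        return [a for a in self.assignments if not a.suppressed]

    @property
    def active_codes(self) -> set[CriterionCode]:
        return {a.code for a in self.active_assignments}
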