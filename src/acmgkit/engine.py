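"""Automatic criterion assignment from pre-annotated variant evidence.

Reproduces the laboratory's automated rule set: gnomAD-style frequency
criteria with inheritance-aware cutoffs (BA1/PM2/BS2/BS1), in-silico
predictor concordance (PP3/BP4) with dbscSNV ADA/RF splice cutoffs,
loss-of-function grading (PVS1) including the NMD/last-exon downgrade,
mutational-hotspot and functional-domain scoring (PM1) with the
disulfide-bond exception, and the remaining database-driven criteria
(PS1, PM4, PM5, BP1/PP2, BP3, PP5/BP6, BP7).

Every rule that withholds a criterion leaves a machine-readable
exclusion record so the reviewer can see exactly why a code is absent.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .config import RunConfig
from .model import (
    CriterionAssignment,
    CriterionCode,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    StrengthLevel,
    clamp_benign_strength,
    default_strength,
)

# dbscSNV splice-predictor cutoffs (scores strictly above → damaging)
ADA_CUTOFF = 0.708
RF_CUTOFF = 0.515

# mutational hotspot: >= HOTSPOT_MIN_COUNT pathogenic missense/in-frame
# neighbors within HOTSPOT_WINDOW_NT coding bases on either side
HOTSPOT_WINDOW_NT = 25
HOTSPOT_MIN_COUNT = 6
DOMAIN_RATIO_CUTOFF = 0.5
PM1_MIN_DOMAIN_VARIANTS = 10

# inheritance-aware population cutoffs
AD_ALLELE_CUTOFF = 5  # PM2 when allele_count < 5 (AD, mixed AD/AR)
AR_HOMOZYGOTE_CUTOFF = 3  # PM2 when homozygotes/hemizygotes < 3 (AR, XL)

MIN_CONCORDANT_PREDICTORS = 3

LOF_CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "initiation_codon"}
)


class AutoAssignmentReport(BaseModel):
    """Output of the automatic engine for one variant."""

    assignments: list[CriterionAssignment] = Field(default_factory=list)
    excluded: list[tuple[CriterionCode, str]] = Field(default_factory=list)
    decision_maf: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "AutoAssignmentReport":
        assigned = {a.code for a in self.assignments}
        if len(assigned) != len(self.assignments):
            raise ValueError("duplicate criterion in auto assignments")
        overlap = assigned & {c for c, _ in self.excluded}
        if overlap:
            raise ValueError(
                f"codes both assigned and excluded: {sorted(c.value for c in overlap)}"
            )
        for a, b in MUTUALLY_EXCLUSIVE_PAIRS:
            if a in assigned and b in assigned:
                raise ValueError(f"mutually exclusive pair co-assigned: {a}/{b}")
        return self

    @property
    def assigned_codes(self) -> set[CriterionCode]:
        return {a.code for a in self.assignments}


MUTUALLY_EXCLUSIVE_PAIRS = (
    (CriterionCode.PP3, CriterionCode.BP4),
    (CriterionCode.BP1, CriterionCode.PP2),
    (CriterionCode.PM2, CriterionCode.BS1),
    (CriterionCode.PM2, CriterionCode.BS2),
    (CriterionCode.BA1, CriterionCode.BS1),
    (CriterionCode.BA1, CriterionCode.BS2),
)


def compute_decision_maf(population: PopulationRecord) -> float:
    """Working allele frequency: the maximum over subpopulations,
    excluding the bottlenecked/founder groups (Finnish, Ashkenazi,
    "other" by default). 0 when no eligible subpopulation reports."""
    excluded = {s.upper() for s in population.excluded_subpops}
    best = 0.0
    for name, freq in population.subpop_frequencies.items():
        if not (0.0 <= freq <= 1.0):
            raise ValueError(f"subpopulation {name!r}: frequency {freq} not in [0,1]")
        if name.upper() in excluded:
            continue
        best = max(best, freq)
    return best


def prefilter(bundle: EvidenceBundle, config: Optional[RunConfig] = None) -> bool:
    """Keep a variant for annotation when its DecisionMAF is strictly
    below the 3% threshold, or when it is on the exception allowlist
    (hypomorphic variants and the benign-filter-exception set)."""
    config = config or RunConfig()
    if bundle.variant_id in config.ba1_exempt:
        return True
    return compute_decision_maf(bundle.population) < config.maf_threshold


def _effective_model(
    gene_context: GeneContext, inheritance_override: Optional[str]
) -> Optional[str]:
    """Resolve the inheritance model to one of AD / AR / XL / AD_AR.

    AD (alone or mixed with anything) and mixed AD/AR use the <5-allele
    branch; AR-only uses homozygotes and XL-only uses hemizygotes
    (both <3). The override handles curated-database discrepancies.
    """
    if inheritance_override:
        return inheritance_override
    inh = gene_context.inheritance
    if not inh:
        return None
    if "AD" in inh and "AR" in inh:
        return "AD_AR"
    if "AD" in inh:
        return "AD"
    if "AR" in inh:
        return "AR"
    return "XL"


def assign_frequency_criteria(
    bundle: EvidenceBundle,
    config: Optional[RunConfig] = None,
    inheritance_override: Optional[str] = None,
) -> tuple[list[CriterionAssignment], list[tuple[CriterionCode, str]]]:
    """Population-frequency criteria: BA1, PM2, BS2, and (when a
    disorder-specific ceiling is configured) BS1.

    BA1 fires above 5% DecisionMAF unless the variant is a known
    hypomorphic/exception allele. PM2/BS2 use inheritance-aware gnomAD
    cutoffs: <5 alleles (AD or mixed AD/AR) or <3 homozygotes (AR) /
    hemizygotes (XL). BS1/BS2 are never emitted alongside BA1 or PM2,
    and BS2 is disabled for late-onset disorders.
    """
    config = config or RunConfig()
    pop = bundle.population
    gc = bundle.gene_context
    maf = compute_decision_maf(pop)
    out: list[CriterionAssignment] = []
    excluded: list[tuple[CriterionCode, str]] = []

    ba1 = False
    if maf > config.ba1_threshold:
        if bundle.variant_id in config.ba1_exempt:
            excluded.append(
                (
                    CriterionCode.BA1,
                    f"allowlisted hypomorphic/exception variant (DecisionMAF {maf:g})",
                )
            )
        else:
            ba1 = True
            out.append(
                CriterionAssignment(
                    code=CriterionCode.BA1,
                    strength=StrengthLevel.STAND_ALONE,
                    rationale=f"DecisionMAF {maf:g} > {config.ba1_threshold:g}",
                )
            )

    model = _effective_model(gc, inheritance_override)
    pm2 = False
    bs2_candidate = False
    if model is None:
        excluded.append(
            (CriterionCode.PM2, "inheritance model unknown for gene context")
        )
        excluded.append(
            (CriterionCode.BS2, "inheritance model unknown for gene context")
        )
    else:
        if model in ("AD", "AD_AR"):
            count, cutoff, what = pop.allele_count, AD_ALLELE_CUTOFF, "allele count"
        elif model == "AR":
            count, cutoff, what = (
                pop.homozygote_count,
                AR_HOMOZYGOTE_CUTOFF,
                "homozygote count",
            )
        else:  # XL
            count, cutoff, what = (
                pop.hemizygote_count,
                AR_HOMOZYGOTE_CUTOFF,
                "hemizygote count",
            )
        if count < cutoff:
            pm2 = True
            out.append(
                CriterionAssignment(
                    code=CriterionCode.PM2,
                    strength=StrengthLevel.MODERATE,
                    rationale=f"{model} model: gnomAD {what} {count} < {cutoff}",
                )
            )
        else:
            bs2_candidate = True

    if bs2_candidate:
        if ba1:
            excluded.append((CriterionCode.BS2, "not evaluated: BA1 active"))
        elif gc.late_onset:
            excluded.append(
                (CriterionCode.BS2, "disabled: late-onset disorder for this gene")
            )
        else:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.BS2,
                    strength=StrengthLevel.STRONG,
                    rationale=f"{model} model: population count at/above PM2 cutoff",
                )
            )

    # BS1: disorder-specific frequency ceiling, config-supplied per gene
    override = config.gene_overrides.get(gc.gene)
    ceiling = override.bs1_frequency_ceiling if override else None
    if ceiling is not None:
        if ba1 or pm2:
            excluded.append((CriterionCode.BS1, "not evaluated: BA1 or PM2 active"))
        elif maf > ceiling:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.BS1,
                    strength=StrengthLevel.STRONG,
                    rationale=f"DecisionMAF {maf:g} > disorder ceiling {ceiling:g}",
                )
            )

    return out, excluded


def assign_predictor_criteria(
    bundle: EvidenceBundle,
    pvs1_active: bool,
    bp7_active: bool = False,
    config: Optional[RunConfig] = None,
) -> tuple[list[CriterionAssignment], list[tuple[CriterionCode, str]]]:
    """In-silico evidence: PP3 / BP4.

    At least three total and concordant predictors are required. Under
    the default ``strict`` policy concordance means zero calls of the
    opposite polarity; under ``majority`` it means >50% of calls in the
    winning polarity (the behavior observed upstream). For intronic
    variants outside canonical sites the dbscSNV splice scores may
    assign PP3 (ADA > 0.708 AND RF > 0.515) or BP4 (both at/below).
    Both criteria are withheld whenever PVS1 is active, and splice
    scores are never used for synonymous variants once BP7 is assigned.
    """
    config = config or RunConfig()
    panel = bundle.predictors
    out: list[CriterionAssignment] = []
    excluded: list[tuple[CriterionCode, str]] = []

    if pvs1_active:
        excluded.append((CriterionCode.PP3, "withheld: PVS1 active"))
        excluded.append((CriterionCode.BP4, "withheld: PVS1 active"))
        return out, excluded

    npath, nben = panel.n_pathogenic_calls, panel.n_benign_calls
    total = npath + nben
    winner: Optional[CriterionCode] = None
    reason = ""
    if total >= 1:
        if config.concordance_mode == "strict":
            if npath >= MIN_CONCORDANT_PREDICTORS and nben == 0:
                winner = CriterionCode.PP3
                reason = f"{npath} concordant pathogenic predictors"
            elif nben >= MIN_CONCORDANT_PREDICTORS and npath == 0:
                winner = CriterionCode.BP4
                reason = f"{nben} concordant benign predictors"
            elif total < MIN_CONCORDANT_PREDICTORS:
                excluded.append(
                    (
                        CriterionCode.PP3 if npath >= nben else CriterionCode.BP4,
                        f"only {total} predictors reporting (<"
                        f"{MIN_CONCORDANT_PREDICTORS} required)",
                    )
                )
            else:
                code = CriterionCode.PP3 if npath >= nben else CriterionCode.BP4
                excluded.append(
                    (
                        code,
                        f"discordant predictors ({npath} pathogenic vs {nben} benign)"
                        " under strict concordance",
                    )
                )
        else:  # majority
            if npath >= MIN_CONCORDANT_PREDICTORS and npath * 2 > total:
                winner = CriterionCode.PP3
                reason = f"majority: {npath}/{total} pathogenic predictors"
            elif nben >= MIN_CONCORDANT_PREDICTORS and nben * 2 > total:
                winner = CriterionCode.BP4
                reason = f"majority: {nben}/{total} benign predictors"
            else:
                code = CriterionCode.PP3 if npath >= nben else CriterionCode.BP4
                excluded.append(
                    (code, f"no ≥{MIN_CONCORDANT_PREDICTORS}-call majority")
                )

    # dbscSNV splice scores for intronic variants outside canonical sites
    consequence = bundle.transcript.consequence
    ada, rf = panel.ada_score, panel.rf_score
    if consequence == "intronic" and ada is not None and rf is not None:
        if winner is None:
            if ada > ADA_CUTOFF and rf > RF_CUTOFF:
                winner = CriterionCode.PP3
                reason = f"splice scores ADA {ada:g} > {ADA_CUTOFF}, RF {rf:g} > {RF_CUTOFF}"
                excluded = [(c, r) for c, r in excluded if c is not CriterionCode.PP3]
            elif ada <= ADA_CUTOFF and rf <= RF_CUTOFF:
                winner = CriterionCode.BP4
                reason = f"splice scores ADA {ada:g} ≤ {ADA_CUTOFF}, RF {rf:g} ≤ {RF_CUTOFF}"
                excluded = [(c, r) for c, r in excluded if c is not CriterionCode.BP4]
    elif consequence == "synonymous" and bp7_active and (ada or rf):
        excluded.append(
            (CriterionCode.PP3, "splice scores not used for synonymous with BP7 active")
        )

    if winner is not None:
        out.append(
            CriterionAssignment(
                code=winner,
                strength=StrengthLevel.SUPPORTING,
                rationale=reason,
            )
        )
    return out, excluded


def grade_pvs1(
    bundle: EvidenceBundle,
) -> tuple[Optional[CriterionAssignment], list[tuple[CriterionCode, str]]]:
    """Loss-of-function criterion with strength grading.

    Applies only to null consequences in genes where LoF is an
    established disease mechanism. Variants at the first/last base of
    an exon are excluded (not canonical splice in the guidelines).
    When nonsense-mediated decay is not predicted (last exon, or last
    50 bp of the penultimate exon) and no other P/LP variants lie
    downstream, the criterion drops to Supporting. Otherwise an
    externally computed strength (e.g. from a dedicated LoF decision
    tree) is honored; the default is VeryStrong.
    """
    tx = bundle.transcript
    excluded: list[tuple[CriterionCode, str]] = []
    if tx.consequence not in LOF_CONSEQUENCES:
        return None, excluded
    if not bundle.gene_context.lof_mechanism:
        excluded.append(
            (CriterionCode.PVS1, "LoF is not a known disease mechanism for this gene")
        )
        return None, excluded
    if tx.consequence == "canonical_splice" and tx.at_exon_first_or_last_base:
        excluded.append(
            (CriterionCode.PVS1, "variant at first/last base of an exon (not canonical)")
        )
        return None, excluded
    if tx.in_last_exon_or_last50bp_penultimate and not tx.downstream_plp_variants:
        return (
            CriterionAssignment(
                code=CriterionCode.PVS1,
                strength=StrengthLevel.SUPPORTING,
                rationale="NMD not predicted (last exon / last 50 bp of "
                "penultimate exon) and no P/LP variants downstream",
            ),
            excluded,
        )
    external = next(
        (
            a
            for a in bundle.externally_supplied_criteria
            if a.code is CriterionCode.PVS1
        ),
        None,
    )
    if external is not None:
        if not external.code.is_pathogenic or external.strength not in (
            StrengthLevel.SUPPORTING,
            StrengthLevel.MODERATE,
            StrengthLevel.STRONG,
            StrengthLevel.VERY_STRONG,
        ):
            raise ValueError("externally supplied PVS1 has invalid strength")
        return (
            CriterionAssignment(
                code=CriterionCode.PVS1,
                strength=external.strength,
                source="external",
                rationale=external.rationale or "externally supplied PVS1 strength",
            ),
            excluded,
        )
    return (
        CriterionAssignment(
            code=CriterionCode.PVS1,
            strength=StrengthLevel.VERY_STRONG,
            rationale=f"{tx.consequence} in LoF-mechanism gene",
        ),
        excluded,
    )


def assign_pm1(
    bundle: EvidenceBundle, config: Optional[RunConfig] = None
) -> tuple[Optional[CriterionAssignment], list[tuple[CriterionCode, str]]]:
    """Mutational hotspot / critical functional domain (PM1).

    Hotspot branch: at least six pathogenic missense/in-frame neighbors
    within 25 coding bases on either side. Domain branch: the variant
    lies in an annotated domain whose pathogenic : non-VUS ratio
    exceeds 0.5 with at least one pathogenic variant. Disulfide-bond
    annotations only involve the two bridge cysteines, so PM1 is
    withheld unless the variant sits on a bond residue. A downgrade to
    Supporting is suggested when the domain holds fewer than 10
    classified variants or is very large.
    """
    config = config or RunConfig()
    dom = bundle.domain
    excluded: list[tuple[CriterionCode, str]] = []

    if dom.is_disulfide_bond_annotation and not dom.variant_at_bond_residue:
        excluded.append(
            (
                CriterionCode.PM1,
                "disulfide-bond annotation involves only the bridge residues; "
                "variant is not at a bond residue",
            )
        )
        return None, excluded

    n_close = sum(
        1 for d in dom.pathogenic_neighbor_distances_nt if d <= HOTSPOT_WINDOW_NT
    )
    if n_close >= HOTSPOT_MIN_COUNT:
        return (
            CriterionAssignment(
                code=CriterionCode.PM1,
                strength=StrengthLevel.MODERATE,
                rationale=f"hotspot: {n_close} pathogenic neighbors within "
                f"{HOTSPOT_WINDOW_NT} nt (proximity weighting not applied; "
                "count rule only)",
            ),
            excluded,
        )

    if dom.in_domain:
        npath, nben = dom.n_pathogenic_in_domain, dom.n_benign_in_domain
        total = npath + nben
        if npath >= 1 and total > 0 and npath / total > DOMAIN_RATIO_CUTOFF:
            downgrade = (
                total < PM1_MIN_DOMAIN_VARIANTS
                or dom.domain_length_aa > config.pm1_domain_size_ceiling
            )
            why = []
            if total < PM1_MIN_DOMAIN_VARIANTS:
                why.append(f"only {total} classified variants in domain (<10)")
            if dom.domain_length_aa > config.pm1_domain_size_ceiling:
                why.append(
                    f"very large domain ({dom.domain_length_aa} aa > "
                    f"{config.pm1_domain_size_ceiling})"
                )
            rationale = (
                f"domain {dom.domain_name or '?'}: {npath}/{total} pathogenic "
                f"(ratio {npath / total:.2f} > {DOMAIN_RATIO_CUTOFF})"
            )
            if downgrade:
                rationale += "; downgrade to Supporting suggested: " + "; ".join(why)
            return (
                CriterionAssignment(
                    code=CriterionCode.PM1,
                    strength=StrengthLevel.MODERATE,
                    rationale=rationale,
                    downgrade_suggested=downgrade,
                ),
                excluded,
            )
    return None, excluded


def assign_remaining_auto(
    bundle: EvidenceBundle, pvs1_active: bool, config: Optional[RunConfig] = None
) -> tuple[list[CriterionAssignment], list[tuple[CriterionCode, str]]]:
    """Database-driven criteria: PS1, PM5, PM4/BP3, BP1/PP2, PP5/BP6, BP7."""
    config = config or RunConfig()
    tx = bundle.transcript
    gc = bundle.gene_context
    db = bundle.clinical_db
    out: list[CriterionAssignment] = []
    excluded: list[tuple[CriterionCode, str]] = []

    # PS1: same amino-acid change as an established pathogenic variant
    if tx.same_aa_change_as_pathogenic:
        if tx.alt_variant_at_residue_classification == "likely_pathogenic":
            out.append(
                CriterionAssignment(
                    code=CriterionCode.PS1,
                    strength=StrengthLevel.SUPPORTING,
                    rationale="same AA change; alternative variant is likely pathogenic",
                )
            )
        else:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.PS1,
                    strength=StrengthLevel.STRONG,
                    rationale="same AA change as established pathogenic variant",
                )
            )
    # PM5: different pathogenic missense at the same residue
    elif (
        tx.consequence == "missense"
        and tx.alt_variant_at_residue_classification == "pathogenic"
    ):
        out.append(
            CriterionAssignment(
                code=CriterionCode.PM5,
                strength=(
                    StrengthLevel.SUPPORTING if tx.pm5_dubious else StrengthLevel.MODERATE
                ),
                rationale="different pathogenic missense change at this residue"
                + (" (dubious case: Supporting)" if tx.pm5_dubious else ""),
            )
        )

    # PM4 / BP3: protein-length changes
    if tx.consequence in ("inframe_indel", "stop_loss"):
        if tx.in_repeat_region_no_function and tx.consequence == "inframe_indel":
            out.append(
                CriterionAssignment(
                    code=CriterionCode.BP3,
                    strength=StrengthLevel.SUPPORTING,
                    rationale="in-frame indel in repeat region without known function",
                )
            )
        elif pvs1_active:
            excluded.append((CriterionCode.PM4, "not applicable: PVS1 active"))
        else:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.PM4,
                    strength=StrengthLevel.MODERATE,
                    rationale=f"protein length change ({tx.consequence}) outside repeats",
                )
            )

    # BP1 / PP2: gene-level missense statistics (mutually exclusive flags)
    if tx.consequence == "missense":
        if gc.low_benign_missense_rate:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.PP2,
                    strength=StrengthLevel.SUPPORTING,
                    rationale="gene has low benign-missense rate and missense mechanism",
                )
            )
        elif gc.truncating_mechanism:
            out.append(
                CriterionAssignment(
                    code=CriterionCode.BP1,
                    strength=StrengthLevel.SUPPORTING,
                    rationale="missense in gene where truncating variants cause disease",
                )
            )

    # PP5 / BP6: reputable-source interpretation, gated on review status
    if db.clinvar_interpretation in ("pathogenic", "benign"):
        code = (
            CriterionCode.PP5
            if db.clinvar_interpretation == "pathogenic"
            else CriterionCode.BP6
        )
        if db.clinvar_review_stars == 0 and not db.other_db_submissions:
            excluded.append(
                (code, "ClinVar review status 0 stars and no other submissions")
            )
        else:
            out.append(
                CriterionAssignment(
                    code=code,
                    strength=StrengthLevel.SUPPORTING,
                    rationale=f"reputable source reports {db.clinvar_interpretation} "
                    f"({db.clinvar_review_stars} stars)",
                )
            )

    # BP7: synonymous with no predicted splice impact
    if tx.consequence == "synonymous" and _no_splice_impact(bundle):
        out.append(
            CriterionAssignment(
                code=CriterionCode.BP7,
                strength=StrengthLevel.SUPPORTING,
                rationale="synonymous variant, no predicted splice impact",
            )
        )

    return out, excluded


def _no_splice_impact(bundle: EvidenceBundle) -> bool:
    ada = bundle.predictors.ada_score
    rf = bundle.predictors.rf_score
    return (ada is None or ada <= ADA_CUTOFF) and (rf is None or rf <= RF_CUTOFF)


def run_auto(
    bundle: EvidenceBundle,
    config: Optional[RunConfig] = None,
    inheritance_override: Optional[str] = None,
) -> AutoAssignmentReport:
    """Run every automatic rule in fixed order
    (PVS1 → frequency → predictors → PM1 → remaining) and merge any
    externally supplied criteria (benign strengths clamped).

    Returns a report whose assignments respect all mutual-exclusion
    invariants; every withheld criterion carries an exclusion reason.
    """
    config = config or RunConfig()
    assignments: list[CriterionAssignment] = []
    excluded: list[tuple[CriterionCode, str]] = []

    pvs1, exc = grade_pvs1(bundle)
    excluded.extend(exc)
    if pvs1 is not None:
        assignments.append(pvs1)
    pvs1_active = pvs1 is not None

    freq, exc = assign_frequency_criteria(bundle, config, inheritance_override)
    assignments.extend(freq)
    excluded.extend(exc)

    bp7_active = (
        bundle.transcript.consequence == "synonymous" and _no_splice_impact(bundle)
    )
    pred, exc = assign_predictor_criteria(bundle, pvs1_active, bp7_active, config)
    assignments.extend(pred)
    excluded.extend(exc)

    pm1, exc = assign_pm1(bundle, config)
    excluded.extend(exc)
    if pm1 is not None:
        assignments.append(pm1)

    rest, exc = assign_remaining_auto(bundle, pvs1_active, config)
    assignments.extend(rest)
    excluded.extend(exc)

    # merge externally supplied criteria (PVS1 already consumed above)
    assigned_codes = {a.code for a in assignments}
    for ext in bundle.externally_supplied_criteria:
        if ext.code is CriterionCode.PVS1 or ext.code in assigned_codes:
            continue
        merged = ext.model_copy(update={"source": "external"})
        if merged.code.is_benign:
            merged = clamp_benign_strength(merged)
        was_excluded = [r for c, r in excluded if c is ext.code]
        if was_excluded:
            merged = merged.model_copy(
                update={
                    "rationale": (merged.rationale + "; " if merged.rationale else "")
                    + f"engine would withhold ({was_excluded[0]}); kept as supplied "
                    "for reviewer decision"
                }
            )
            excluded = [(c, r) for c, r in excluded if c is not ext.code]
        # honor mutual exclusions: drop external code conflicting with engine output
        conflict = False
        for a, b in MUTUALLY_EXCLUSIVE_PAIRS:
            partner = b if merged.code is a else (a if merged.code is b else None)
            if partner is not None and partner in assigned_codes:
                excluded.append(
                    (merged.code, f"external supply conflicts with assigned {partner.value}")
                )
                conflict = True
                break
        if conflict:
            continue
        assignments.append(merged)
        assigned_codes.add(merged.code)

    # dedupe exclusion records, drop any for assigned codes
    seen: set[CriterionCode] = set()
    final_excluded: list[tuple[CriterionCode, str]] = []
    for c, r in excluded:
        if c in assigned_codes or c in seen:
            continue
        seen.add(c)
        final_excluded.append((c, r))

    return AutoAssignmentReport(
        assignments=assignments,
        excluded=final_excluded,
        decision_maf=compute_decision_maf(bundle.population),
    )
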