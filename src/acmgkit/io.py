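"""Tab-separated evidence / adjustment / report I/O and report tiering.

The evidence table carries one variant per row with a documented header
(see :data:`EVIDENCE_COLUMNS`). Missing optional columns become absent
evidence. Reports are deterministic: identical input, configuration,
and seed produce byte-identical output.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import pandas as pd

from .config import RunConfig
from .model import (
    ClassificationResult,
    ClinicalDbContext,
    CriterionAssignment,
    CriterionCode,
    DomainContext,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    PredictorPanel,
    ReportTier,
    StrengthLevel,
    TranscriptContext,
    Verdict,
    default_strength,
    strength_from_label,
    Adjustment,
)

logger = logging.getLogger("acmgkit")

EVIDENCE_COLUMNS = [
    "variant_id",
    "gene",
    "inheritance",
    "late_onset",
    "phenotype_gene_count",
    "single_gene_disorder",
    "lof_mechanism",
    "high_penetrance",
    "low_benign_missense_rate",
    "truncating_mechanism",
    "subpop_frequencies",
    "allele_count",
    "homozygote_count",
    "hemizygote_count",
    "n_pathogenic_predictors",
    "n_benign_predictors",
    "ada_score",
    "rf_score",
    "in_domain",
    "domain_name",
    "domain_length_aa",
    "n_pathogenic_in_domain",
    "n_benign_in_domain",
    "disulfide_annotation",
    "at_bond_residue",
    "hotspot_distances_nt",
    "consequence",
    "at_exon_edge",
    "in_last_exon_or_last50bp",
    "downstream_plp",
    "repeat_region_no_function",
    "same_aa_as_pathogenic",
    "alt_residue_classification",
    "pm5_dubious",
    "clinvar_stars",
    "clinvar_interpretation",
    "other_db_submissions",
    "external_criteria",
]

REPORT_COLUMNS = [
    "variant_id",
    "verdict",
    "report_tier",
    "phenotype_modifier",
    "decision_maf",
    "active_criteria",
    "suppressed_criteria",
    "excluded_criteria",
    "matched_clause",
    "adjustments",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if pd.isna(v):
        return False
    return _BOOL[str(v).strip().lower()]


def _parse_freqs(v) -> dict[str, float]:
    if v is None or (not isinstance(v, str) and pd.isna(v)) or str(v).strip() == "":
        return {}
    out = {}
    for part in str(v).split(","):
        name, _, freq = part.partition(":")
        out[name.strip()] = float(freq)
    return out


def _format_freqs(freqs: dict[str, float]) -> str:
    return ",".join(f"{k}:{freqs[k]!r}" for k in sorted(freqs))


def _parse_criteria(v) -> list[CriterionAssignment]:
    if v is None or (not isinstance(v, str) and pd.isna(v)) or str(v).strip() == "":
        return []
    out = []
    for token in str(v).split(";"):
        token = token.strip()
        if not token:
            continue
        code, _, strength = token.partition("@")
        out.append(
            CriterionAssignment(
                code=CriterionCode(code),
                strength=(
                    strength_from_label(strength)
                    if strength
                    else default_strength(CriterionCode(code))
                ),
                source="external",
            )
        )
    return out


def _format_criteria(assignments: Iterable[CriterionAssignment]) -> str:
    return ";".join(f"{a.code.value}@{a.strength.label()}" for a in assignments)


def _opt_float(v) -> Optional[float]:
    if v is None or (not isinstance(v, str) and pd.isna(v)) or str(v).strip() == "":
        return None
    return float(v)


def _int(v, default: int = 0) -> int:
    if v is None or (not isinstance(v, str) and pd.isna(v)) or str(v).strip() == "":
        return default
    return int(float(v))


def bundle_from_row(row: dict) -> EvidenceBundle:
    """Build an EvidenceBundle from one evidence-table row."""
    inheritance = {
        m.strip()
        for m in str(row.get("inheritance") or "").split(",")
        if m.strip()
    }
    gc = GeneContext(
        gene=str(row.get("gene") or ""),
        inheritance=inheritance,  # type: ignore[arg-type]
        late_onset=_parse_bool(row.get("late_onset")),
        phenotype_gene_count=_int(row.get("phenotype_gene_count")),
        single_gene_disorder=_parse_bool(row.get("single_gene_disorder")),
        lof_mechanism=_parse_bool(row.get("lof_mechanism")),
        high_penetrance=_parse_bool(row.get("high_penetrance")),
        low_benign_missense_rate=_parse_bool(row.get("low_benign_missense_rate")),
        truncating_mechanism=_parse_bool(row.get("truncating_mechanism")),
    )
    pop = PopulationRecord(
        subpop_frequencies=_parse_freqs(row.get("subpop_frequencies")),
        allele_count=_int(row.get("allele_count")),
        homozygote_count=_int(row.get("homozygote_count")),
        hemizygote_count=_int(row.get("hemizygote_count")),
    )
    panel = PredictorPanel(
        n_pathogenic_calls=_int(row.get("n_pathogenic_predictors")),
        n_benign_calls=_int(row.get("n_benign_predictors")),
        ada_score=_opt_float(row.get("ada_score")),
        rf_score=_opt_float(row.get("rf_score")),
    )
    hotspots = [
        int(x)
        for x in str(row.get("hotspot_distances_nt") or "").split(",")
        if str(x).strip()
    ]
    dom = DomainContext(
        in_domain=_parse_bool(row.get("in_domain")),
        domain_name=str(row.get("domain_name") or ""),
        domain_length_aa=_int(row.get("domain_length_aa"), default=1) or 1,
        n_pathogenic_in_domain=_int(row.get("n_pathogenic_in_domain")),
        n_benign_in_domain=_int(row.get("n_benign_in_domain")),
        is_disulfide_bond_annotation=_parse_bool(row.get("disulfide_annotation")),
        variant_at_bond_residue=_parse_bool(row.get("at_bond_residue")),
        pathogenic_neighbor_distances_nt=hotspots,
    )
    tx = TranscriptContext(
        consequence=str(row.get("consequence") or "other"),  # type: ignore[arg-type]
        at_exon_first_or_last_base=_parse_bool(row.get("at_exon_edge")),
        in_last_exon_or_last50bp_penultimate=_parse_bool(
            row.get("in_last_exon_or_last50bp")
        ),
        downstream_plp_variants=_parse_bool(row.get("downstream_plp")),
        in_repeat_region_no_function=_parse_bool(row.get("repeat_region_no_function")),
        same_aa_change_as_pathogenic=_parse_bool(row.get("same_aa_as_pathogenic")),
        alt_variant_at_residue_classification=str(
            row.get("alt_residue_classification") or "none"
        ),  # type: ignore[arg-type]
        pm5_dubious=_parse_bool(row.get("pm5_dubious")),
    )
    db = ClinicalDbContext(
        clinvar_review_stars=_int(row.get("clinvar_stars")),
        clinvar_interpretation=str(
            row.get("clinvar_interpretation") or "none"
        ),  # type: ignore[arg-type]
        other_db_submissions=_parse_bool(row.get("other_db_submissions")),
    )
    return EvidenceBundle(
        variant_id=str(row["variant_id"]),
        gene_context=gc,
        population=pop,
        predictors=panel,
        domain=dom,
        transcript=tx,
        clinical_db=db,
        externally_supplied_criteria=_parse_criteria(row.get("external_criteria")),
    )


def bundle_to_row(bundle: EvidenceBundle) -> dict:
    """Serialize an EvidenceBundle to a flat evidence-table row."""
    gc, pop, panel = bundle.gene_context, bundle.population, bundle.predictors
    dom, tx, db = bundle.domain, bundle.transcript, bundle.clinical_db
    return {
        "variant_id": bundle.variant_id,
        "gene": gc.gene,
        "inheritance": ",".join(sorted(gc.inheritance)),
        "late_onset": gc.late_onset,
        "phenotype_gene_count": gc.phenotype_gene_count,
        "single_gene_disorder": gc.single_gene_disorder,
        "lof_mechanism": gc.lof_mechanism,
        "high_penetrance": gc.high_penetrance,
        "low_benign_missense_rate": gc.low_benign_missense_rate,
        "truncating_mechanism": gc.truncating_mechanism,
        "subpop_frequencies": _format_freqs(pop.subpop_frequencies),
        "allele_count": pop.allele_count,
        "homozygote_count": pop.homozygote_count,
        "hemizygote_count": pop.hemizygote_count,
        "n_pathogenic_predictors": panel.n_pathogenic_calls,
        "n_benign_predictors": panel.n_benign_calls,
        "ada_score": "" if panel.ada_score is None else repr(panel.ada_score),
        "rf_score": "" if panel.rf_score is None else repr(panel.rf_score),
        "in_domain": dom.in_domain,
        "domain_name": dom.domain_name,
        "domain_length_aa": dom.domain_length_aa,
        "n_pathogenic_in_domain": dom.n_pathogenic_in_domain,
        "n_benign_in_domain": dom.n_benign_in_domain,
        "disulfide_annotation": dom.is_disulfide_bond_annotation,
        "at_bond_residue": dom.variant_at_bond_residue,
        "hotspot_distances_nt": ",".join(
            str(d) for d in dom.pathogenic_neighbor_distances_nt
        ),
        "consequence": tx.consequence,
        "at_exon_edge": tx.at_exon_first_or_last_base,
        "in_last_exon_or_last50bp": tx.in_last_exon_or_last50bp_penultimate,
        "downstream_plp": tx.downstream_plp_variants,
        "repeat_region_no_function": tx.in_repeat_region_no_function,
        "same_aa_as_pathogenic": tx.same_aa_change_as_pathogenic,
        "alt_residue_classification": tx.alt_variant_at_residue_classification,
        "pm5_dubious": tx.pm5_dubious,
        "clinvar_stars": db.clinvar_review_stars,
        "clinvar_interpretation": db.clinvar_interpretation,
        "other_db_submissions": db.other_db_submissions,
        "external_criteria": _format_criteria(bundle.externally_supplied_criteria),
    }


def read_evidence_table(path: str) -> list[EvidenceBundle]:
    """Read a TSV evidence table into bundles.

    Malformed rows raise with their line number; unknown columns only
    warn. Missing optional columns become absent evidence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(EVIDENCE_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown evidence columns: %s", sorted(unknown))
    if "variant_id" not in df.columns:
        raise ValueError(f"{path}: evidence table lacks required column 'variant_id'")
    bundles = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            bundles.append(bundle_from_row(row))
        except Exception as exc:  # noqa: BLE001 - re-raise with location
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return bundles


def write_evidence_table(bundles: list[EvidenceBundle], path: str) -> None:
    df = pd.DataFrame([bundle_to_row(b) for b in bundles], columns=EVIDENCE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_adjustments(path: str) -> dict[str, list[Adjustment]]:
    """Adjustment TSV: variant_id, code, action, strength, justification."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[Adjustment]] = {}
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            strength = row.get("strength", "")
            adj = Adjustment(
                code=CriterionCode(row["code"]),
                action=row["action"],  # type: ignore[arg-type]
                new_strength=strength_from_label(strength) if strength else None,
                justification=row["justification"],
            )
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
        out.setdefault(str(row["variant_id"]), []).append(adj)
    return out


def assign_report_tier(
    verdict: Verdict,
    gene_context: GeneContext,
    allele_count: int,
    phenotype_modifier: bool = False,
) -> ReportTier:
    """Primary/secondary clinical-report tier.

    Primary: any P/LP variant in AD or AR genes, or a VUS in AD-only
    genes. Secondary: a VUS in AR-only genes, or a VUS in mixed AD/AR
    genes with ≥5 heterozygotes in gnomAD. X-linked genes follow the
    recessive-like branch. Benign/LikelyBenign variants are not
    reported (allowlisted hypomorphic alleles are carried through as
    phenotype modifiers, flagged separately in the report).
    """
    if verdict in (Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC):
        return ReportTier.PRIMARY
    if verdict is Verdict.UNCERTAIN:
        inh = gene_context.inheritance
        if "AD" in inh and "AR" in inh:
            return ReportTier.SECONDARY if allele_count >= 5 else ReportTier.PRIMARY
        if "AD" in inh:
            return ReportTier.PRIMARY
        # AR-only and XL follow the recessive-like branch
        return ReportTier.SECONDARY
    # Benign / LikelyBenign
    return ReportTier.NOT_REPORTED


def filter_for_report(
    results: list[ClassificationResult], config: Optional[RunConfig] = None
) -> list[ClassificationResult]:
    """Drop automatic Benign/LikelyBenign verdicts, keeping allowlisted
    exception variants (reported as phenotype modifiers). Order is
    preserved; drop counts are logged."""
    config = config or RunConfig()
    kept: list[ClassificationResult] = []
    dropped = 0
    for r in results:
        auto = r.auto_verdict or r.verdict
        if auto in (Verdict.BENIGN, Verdict.LIKELY_BENIGN):
            if r.variant_id in config.ba1_exempt:
                kept.append(r.model_copy(update={"phenotype_modifier": True}))
            else:
                dropped += 1
        else:
            kept.append(r)
    logger.info("benign filter: dropped %d variant(s), kept %d", dropped, len(kept))
    return kept


def result_to_row(result: ClassificationResult) -> dict:
    active = sorted(result.active_assignments, key=lambda a: a.code.value)
    suppressed = sorted(
        (a for a in result.assignments if a.suppressed), key=lambda a: a.code.value
    )
    return {
        "variant_id": result.variant_id,
        "verdict": result.verdict.value,
        "report_tier": result.report_tier.value if result.report_tier else "",
        "phenotype_modifier": result.phenotype_modifier,
        "decision_maf": repr(result.decision_maf),
        "active_criteria": _format_criteria(active),
        "suppressed_criteria": _format_criteria(suppressed),
        "excluded_criteria": ";".join(
            f"{c.value}[{r}]" for c, r in sorted(result.excluded, key=lambda x: x[0].value)
        ),
        "matched_clause": result.matched_clause,
        "adjustments": ";".join(
            f"{a.action}:{a.code.value}"
            + (f"@{a.new_strength.label()}" if a.new_strength else "")
            for a in result.adjustments_applied
        ),
    }


def write_report(results: list[ClassificationResult], path: str) -> None:
    """Deterministic TSV report: fixed column order, input row order."""
    df = pd.DataFrame([result_to_row(r) for r in results], columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
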