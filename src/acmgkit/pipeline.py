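"""End-to-end helpers tying engine, combiner, review, and tiering together."""

from __future__ import annotations

from typing import Optional

from .combine import classify_with_audit
from .config import RunConfig
from .engine import run_auto
from .io import assign_report_tier, filter_for_report
from .model import Adjustment, ClassificationResult, EvidenceBundle, GeneContext
from .review import ChecklistPolicy, apply_adjustments


def classify_bundle(
    bundle: EvidenceBundle,
    config: Optional[RunConfig] = None,
    inheritance_override: Optional[str] = None,
) -> ClassificationResult:
    """Automatic classification of one variant: criterion assignment,
    combination, and report tiering, with the full audit trail."""
    config = config or RunConfig()
    report = run_auto(bundle, config, inheritance_override)
    result = classify_with_audit(report.assignments, variant_id=bundle.variant_id)
    tier = assign_report_tier(
        result.verdict, bundle.gene_context, bundle.population.allele_count
    )
    return result.model_copy(
        update={
            "excluded": report.excluded,
            "decision_maf": report.decision_maf,
            "report_tier": tier,
            "auto_verdict": result.verdict,
            "phenotype_modifier": bundle.variant_id in config.ba1_exempt
            and result.verdict.value in ("Benign", "LikelyBenign"),
        }
    )


def review_bundle(
    bundle: EvidenceBundle,
    adjustments: list[Adjustment],
    config: Optional[RunConfig] = None,
    policy: Optional[ChecklistPolicy] = None,
    inheritance_override: Optional[str] = None,
) -> ClassificationResult:
    """Automatic classification followed by reviewer adjustments."""
    config = config or RunConfig()
    auto = classify_bundle(bundle, config, inheritance_override)
    if not adjustments:
        return auto
    final = apply_adjustments(auto, adjustments, policy, bundle.gene_context)
    tier = assign_report_tier(
        final.verdict, bundle.gene_context, bundle.population.allele_count
    )
    return final.model_copy(update={"report_tier": tier})


def classify_table(
    bundles: list[EvidenceBundle],
    config: Optional[RunConfig] = None,
    inheritance_overrides: Optional[dict[str, str]] = None,
    apply_benign_filter: bool = True,
) -> list[ClassificationResult]:
    """Classify a list of bundles, then apply the benign report filter."""
    config = config or RunConfig()
    overrides = inheritance_overrides or {}
    results = [
        classify_bundle(b, config, overrides.get(b.gene_context.gene)) for b in bundles
    ]
    if apply_benign_filter:
        results = filter_for_report(results, config)
    return results
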