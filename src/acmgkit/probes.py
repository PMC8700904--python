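"""Boundary-recovery probes.

Each probe drives one engine rule with a monotone sweep (or bisection
for real-valued scores) over its decisive input and returns the
boundary the live engine actually exhibits. Used by the verification
script and the acceptance tests: a probe recovering the documented
cutoff shows the rule is wired to the right comparison, not just that a
constant is stored somewhere.
"""

from __future__ import annotations

from .config import RunConfig
from .engine import (
    assign_frequency_criteria,
    assign_pm1,
    assign_predictor_criteria,
    prefilter,
)
from .model import (
    CriterionCode,
    DomainContext,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    PredictorPanel,
    TranscriptContext,
)

C = CriterionCode


def _bisect_boundary(predicate, lo: float, hi: float, tol: float = 1e-9) -> float:
    """Smallest x in [lo, hi] with predicate(x) true, assuming monotone
    false→true; found by bisection."""
    assert not predicate(lo) and predicate(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return hi


def prefilter_boundary() -> float:
    """Largest-infimum MAF at which a variant stops being selected."""

    def dropped(maf: float) -> bool:
        b = EvidenceBundle(
            variant_id="probe",
            population=PopulationRecord(subpop_frequencies={"NFE": maf}),
        )
        return not prefilter(b)

    return _bisect_boundary(dropped, 0.0, 1.0)


def ba1_boundary() -> float:
    """Infimum DecisionMAF that triggers the stand-alone benign criterion."""

    def fired(maf: float) -> bool:
        b = EvidenceBundle(
            variant_id="probe",
            gene_context=GeneContext(gene="G", inheritance={"AD"}, late_onset=True),
            population=PopulationRecord(
                subpop_frequencies={"NFE": maf}, allele_count=100
            ),
        )
        out, _ = assign_frequency_criteria(b)
        return C.BA1 in {a.code for a in out}

    return _bisect_boundary(fired, 0.0, 1.0)


def _freq_probe(model: str, field: str, value: int) -> bool:
    pop = {"allele_count": 0, "homozygote_count": 0, "hemizygote_count": 0}
    pop[field] = value
    inh = {"AD": {"AD"}, "AR": {"AR"}, "XL": {"XL"}}[model]
    b = EvidenceBundle(
        variant_id="probe",
        gene_context=GeneContext(gene="G", inheritance=inh),
        population=PopulationRecord(**pop),
    )
    out, _ = assign_frequency_criteria(b)
    return C.PM2 in {a.code for a in out}


def pm2_ad_allele_cutoff() -> int:
    """Smallest allele count at which PM2 stops firing under a dominant model."""
    return next(n for n in range(0, 100) if not _freq_probe("AD", "allele_count", n))


def pm2_ar_homozygote_cutoff() -> int:
    """Smallest homozygote count at which PM2 stops firing under a
    recessive model (hemizygotes behave identically for X-linked)."""
    ar = next(n for n in range(0, 100) if not _freq_probe("AR", "homozygote_count", n))
    xl = next(n for n in range(0, 100) if not _freq_probe("XL", "hemizygote_count", n))
    assert ar == xl
    return ar


def min_concordant_predictors() -> int:
    """Smallest number of unanimous pathogenic calls that assigns PP3."""

    def fired(n: int) -> bool:
        b = EvidenceBundle(
            variant_id="probe",
            predictors=PredictorPanel(n_pathogenic_calls=n),
            transcript=TranscriptContext(consequence="missense"),
        )
        out, _ = assign_predictor_criteria(b, pvs1_active=False)
        return C.PP3 in {a.code for a in out}

    return next(n for n in range(0, 50) if fired(n))


def _splice_fired(ada: float, rf: float) -> bool:
    b = EvidenceBundle(
        variant_id="probe",
        predictors=PredictorPanel(ada_score=ada, rf_score=rf),
        transcript=TranscriptContext(consequence="intronic"),
    )
    out, _ = assign_predictor_criteria(b, pvs1_active=False)
    return C.PP3 in {a.code for a in out}


def ada_cutoff() -> float:
    """Infimum ADA score assigning PP3 to an intronic variant (RF held high)."""
    return _bisect_boundary(lambda x: _splice_fired(x, 0.99), 0.0, 1.0)


def rf_cutoff() -> float:
    """Infimum RF score assigning PP3 to an intronic variant (ADA held high)."""
    return _bisect_boundary(lambda x: _splice_fired(0.99, x), 0.0, 1.0)


def _hotspot_fired(n: int, distance: int) -> bool:
    b = EvidenceBundle(
        variant_id="probe",
        domain=DomainContext(pathogenic_neighbor_distances_nt=[distance] * n),
    )
    a, _ = assign_pm1(b)
    return a is not None


def hotspot_min_count() -> int:
    """Smallest pathogenic-neighbor count triggering the hotspot rule."""
    return next(n for n in range(0, 50) if _hotspot_fired(n, 0))


def hotspot_window_nt() -> int:
    """Largest neighbor distance still counted by the hotspot rule."""
    last = None
    for d in range(0, 200):
        if _hotspot_fired(6, d):
            last = d
        else:
            break
    assert last is not None
    return last


def domain_ratio_boundary(denominator: int = 1000) -> float:
    """Infimum pathogenic fraction (at fixed denominator) triggering the
    functional-domain rule."""

    def fired(npath: int) -> bool:
        b = EvidenceBundle(
            variant_id="probe",
            domain=DomainContext(
                in_domain=True,
                domain_length_aa=100,
                n_pathogenic_in_domain=npath,
                n_benign_in_domain=denominator - npath,
            ),
        )
        a, _ = assign_pm1(b)
        return a is not None

    npath = next(n for n in range(0, denominator + 1) if fired(n))
    # rule uses a strict ">" comparison: the infimum fraction is the
    # midpoint between the last failing and first firing count
    return (npath - 1) / denominator


def combination_rule_checks() -> dict[str, bool]:
    """Spot checks of the modified combination rules."""
    from .combine import classify
    from .model import StrengthTally, Verdict

    return {
        "one_moderate_three_supporting_is_likely_pathogenic": classify(
            StrengthTally(n_pm=1, n_pp=3)
        )
        is Verdict.LIKELY_PATHOGENIC,
        "two_very_strong_is_pathogenic": classify(StrengthTally(n_pvs=2))
        is Verdict.PATHOGENIC,
        "one_very_strong_one_moderate_one_supporting_is_pathogenic": classify(
            StrengthTally(n_pvs=1, n_pm=1, n_pp=1)
        )
        is Verdict.PATHOGENIC,
    }
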