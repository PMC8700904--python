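"""Automatic criterion assignment: frequency, predictors, LoF, hotspot rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acmgkit import (
    CriterionAssignment,
    CriterionCode,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    PredictorPanel,
    RunConfig,
    StrengthLevel,
    TranscriptContext,
    compute_decision_maf,
    prefilter,
    run_auto,
)
from acmgkit.engine import (
    MUTUALLY_EXCLUSIVE_PAIRS,
    assign_frequency_criteria,
    assign_pm1,
    assign_predictor_criteria,
    grade_pvs1,
)
from acmgkit.model import DomainContext

C = CriterionCode


def bundle(**kw) -> EvidenceBundle:
    kw.setdefault("variant_id", "NM_000000(TEST):c.1A>G")
    return EvidenceBundle(**kw)


# ---------------------------------------------------------------- DecisionMAF


@pytest.mark.parametrize(
    "freqs,expected",
    [
        ({"NFE": 0.02, "FIN": 0.30}, 0.02),
        ({}, 0.0),
        ({"NFE": 0.01, "AFR": 0.04, "ASJ": 0.9}, 0.04),
        ({"FIN": 0.5, "ASJ": 0.4, "OTH": 0.3}, 0.0),
        ({"nfe": 0.01, "fin": 0.99}, 0.01),  # case-insensitive exclusion
    ],
)
def test_decision_maf_excludes_founder_subpops(freqs, expected):
    assert compute_decision_maf(PopulationRecord(subpop_frequencies=freqs)) == expected


def test_decision_maf_rejects_out_of_range_frequency_naming_subpop():
    pop = PopulationRecord.model_construct(
        subpop_frequencies={"NFE": 1.3},
        excluded_subpops={"FIN"},
        allele_count=0,
        homozygote_count=0,
        hemizygote_count=0,
    )
    with pytest.raises(ValueError, match="NFE"):
        compute_decision_maf(pop)


# ------------------------------------------------------------------ prefilter


@pytest.mark.parametrize("maf,kept", [(0.029, True), (0.03, False), (0.0299999, True)])
def test_prefilter_boundary_is_strictly_below_3_percent(maf, kept):
    b = bundle(population=PopulationRecord(subpop_frequencies={"NFE": maf}))
    assert prefilter(b) is kept


def test_prefilter_keeps_allowlisted_hypomorphic_variant():
    b = bundle(
        variant_id="NM_000350(ABCA4):c.5603A>T",
        population=PopulationRecord(subpop_frequencies={"NFE": 0.07}),
    )
    assert prefilter(b) is True


# --------------------------------------------------------- frequency criteria


def freq_bundle(inheritance, ac=0, hom=0, hemi=0, maf=0.0, late=False, vid=None):
    return bundle(
        variant_id=vid or "NM_000000(TEST):c.1A>G",
        gene_context=GeneContext(gene="TEST", inheritance=inheritance, late_onset=late),
        population=PopulationRecord(
            subpop_frequencies={"NFE": maf} if maf else {},
            allele_count=ac,
            homozygote_count=hom,
            hemizygote_count=hemi,
        ),
    )


def freq_codes(b, override=None):
    out, _ = assign_frequency_criteria(b, inheritance_override=override)
    return {a.code for a in out}


@pytest.mark.parametrize(
    "inh,ac,hom,hemi,expected",
    [
        ({"AD"}, 4, 0, 0, {C.PM2}),
        ({"AD"}, 5, 0, 0, {C.BS2}),
        ({"AD"}, 13, 0, 0, {C.BS2}),  # dominant gene, 13 gnomAD alleles
        ({"AD", "AR"}, 4, 9, 0, {C.PM2}),  # mixed model counts alleles
        ({"AD", "AR"}, 5, 0, 0, {C.BS2}),
        ({"AR"}, 100, 2, 0, {C.PM2}),  # recessive: homozygotes decide
        ({"AR"}, 100, 3, 0, {C.BS2}),
        ({"XL"}, 100, 0, 2, {C.PM2}),  # X-linked: hemizygotes decide
        ({"XL"}, 100, 0, 3, {C.BS2}),
    ],
)
def test_inheritance_aware_pm2_bs2_cutoffs(inh, ac, hom, hemi, expected):
    assert freq_codes(freq_bundle(inh, ac=ac, hom=hom, hemi=hemi)) == expected


def test_inheritance_override_flips_dominant_call_to_recessive():
    # dominant per the curated database: 13 alleles → BS2 (likely benign)
    b = freq_bundle({"AD"}, ac=13, hom=0)
    assert freq_codes(b) == {C.BS2}
    # recessive override for the suspected phenotype: 0 homozygotes → PM2
    assert freq_codes(b, override="AR") == {C.PM2}


def test_late_onset_disables_bs2():
    b = freq_bundle({"AD"}, ac=50, late=True)
    out, excluded = assign_frequency_criteria(b)
    assert not out
    assert any(c is C.BS2 and "late-onset" in r for c, r in excluded)


def test_missing_inheritance_is_excluded_not_error():
    b = freq_bundle(set(), ac=0)
    out, excluded = assign_frequency_criteria(b)
    assert not out
    assert {c for c, _ in excluded} == {C.PM2, C.BS2}


@pytest.mark.parametrize("maf,ba1", [(0.051, True), (0.05, False), (0.27, True)])
def test_ba1_boundary_strictly_above_5_percent(maf, ba1):
    codes = freq_codes(freq_bundle({"AD"}, ac=1000, maf=maf, late=True))
    assert (C.BA1 in codes) is ba1


def test_ba1_exempt_for_allowlisted_hypomorphic_variants():
    for vid, maf in [
        ("NM_000350(ABCA4):c.5603A>T", 0.07),
        ("NM_000372(TYR):c.1205G>A", 0.27),
    ]:
        b = freq_bundle({"AR"}, ac=10000, hom=500, maf=maf, vid=vid)
        out, excluded = assign_frequency_criteria(b)
        assert C.BA1 not in {a.code for a in out}
        assert any(c is C.BA1 and "allowlist" in r for c, r in excluded)


def test_bs1_requires_configured_disorder_ceiling():
    from acmgkit.config import GeneOverride

    b = freq_bundle({"AD"}, ac=50, maf=0.01, late=True)
    out, _ = assign_frequency_criteria(b)
    assert C.BS1 not in {a.code for a in out}  # no ceiling → never auto-assigned
    cfg = RunConfig(gene_overrides={"TEST": GeneOverride(bs1_frequency_ceiling=0.005)})
    out, _ = assign_frequency_criteria(b, cfg)
    assert C.BS1 in {a.code for a in out}


# --------------------------------------------------------- predictor criteria


def pred_bundle(npath=0, nben=0, ada=None, rf=None, consequence="missense"):
    return bundle(
        predictors=PredictorPanel(
            n_pathogenic_calls=npath, n_benign_calls=nben, ada_score=ada, rf_score=rf
        ),
        transcript=TranscriptContext(consequence=consequence),
    )


def pred_codes(b, pvs1=False, bp7=False, mode="strict"):
    out, _ = assign_predictor_criteria(
        b, pvs1, bp7, RunConfig(concordance_mode=mode)
    )
    return {a.code for a in out}


@pytest.mark.parametrize(
    "npath,nben,expected",
    [
        (3, 0, {C.PP3}),
        (2, 0, set()),  # below the 3-predictor minimum
        (1, 0, set()),  # single predictor never suffices
        (0, 3, {C.BP4}),
        (0, 2, set()),
        (7, 5, set()),  # discordant under strict concordance
        (0, 0, set()),
    ],
)
def test_strict_concordance_requires_3_calls_and_no_dissent(npath, nben, expected):
    assert pred_codes(pred_bundle(npath, nben)) == expected


def test_majority_mode_reproduces_upstream_7v5_behavior():
    assert pred_codes(pred_bundle(7, 5), mode="majority") == {C.PP3}
    assert pred_codes(pred_bundle(2, 1), mode="majority") == set()  # <3 winners


def test_pp3_bp4_withheld_when_pvs1_active():
    out, excluded = assign_predictor_criteria(pred_bundle(5, 0), pvs1_active=True)
    assert not out
    assert {c for c, _ in excluded} == {C.PP3, C.BP4}


@pytest.mark.parametrize(
    "ada,rf,expected",
    [
        (0.80, 0.60, {C.PP3}),
        (0.709, 0.516, {C.PP3}),  # just above both cutoffs
        (0.708, 0.60, set()),  # ADA at cutoff: not above → mixed signal
        (0.80, 0.515, set()),  # RF at cutoff: not above → mixed signal
        (0.50, 0.40, {C.BP4}),  # both at/below → benign call
    ],
)
def test_splice_score_cutoffs_for_intronic_variants(ada, rf, expected):
    assert pred_codes(pred_bundle(ada=ada, rf=rf, consequence="intronic")) == expected


def test_splice_scores_not_used_for_missense():
    assert pred_codes(pred_bundle(ada=0.9, rf=0.9, consequence="missense")) == set()


# ------------------------------------------------------------------ PVS1


def lof_bundle(consequence="nonsense", lof=True, last_exon=False, downstream=False,
               edge=False, external=None):
    return bundle(
        gene_context=GeneContext(gene="G", inheritance={"AD"}, lof_mechanism=lof),
        transcript=TranscriptContext(
            consequence=consequence,
            at_exon_first_or_last_base=edge,
            in_last_exon_or_last50bp_penultimate=last_exon,
            downstream_plp_variants=downstream,
        ),
        externally_supplied_criteria=external or [],
    )


def test_pvs1_default_very_strong_for_nmd_predicted_null():
    a, _ = grade_pvs1(lof_bundle())
    assert a is not None and a.strength is StrengthLevel.VERY_STRONG


def test_pvs1_supporting_when_nmd_escape_and_no_downstream_plp():
    a, _ = grade_pvs1(lof_bundle(last_exon=True))
    assert a is not None and a.strength is StrengthLevel.SUPPORTING
    a, _ = grade_pvs1(lof_bundle(last_exon=True, downstream=True))
    assert a is not None and a.strength is StrengthLevel.VERY_STRONG


def test_pvs1_none_for_non_lof_consequence_or_mechanism():
    a, _ = grade_pvs1(lof_bundle(consequence="missense"))
    assert a is None
    a, excluded = grade_pvs1(lof_bundle(lof=False))
    assert a is None and excluded


def test_pvs1_excluded_at_exon_first_or_last_base():
    a, excluded = grade_pvs1(lof_bundle(consequence="canonical_splice", edge=True))
    assert a is None
    assert any(c is C.PVS1 for c, _ in excluded)


def test_pvs1_honors_external_strength():
    ext = [CriterionAssignment(code=C.PVS1, strength=StrengthLevel.MODERATE,
                               source="external")]
    a, _ = grade_pvs1(lof_bundle(external=ext))
    assert a is not None and a.strength is StrengthLevel.MODERATE
    assert a.source == "external"


# ------------------------------------------------------------------ PM1


def test_pm1_hotspot_boundary_6_neighbors_within_25nt():
    hot = bundle(domain=DomainContext(pathogenic_neighbor_distances_nt=[25] * 6))
    a, _ = assign_pm1(hot)
    assert a is not None and a.strength is StrengthLevel.MODERATE
    for distances in ([26] * 6, [25] * 5):
        a, _ = assign_pm1(
            bundle(domain=DomainContext(pathogenic_neighbor_distances_nt=distances))
        )
        assert a is None


def test_pm1_domain_ratio_rule():
    # 15 pathogenic vs 8 benign: ratio 0.652 > 0.5 → assigned
    a, _ = assign_pm1(
        bundle(
            domain=DomainContext(
                in_domain=True, domain_length_aa=1056,
                n_pathogenic_in_domain=15, n_benign_in_domain=8,
            )
        )
    )
    assert a is not None and a.downgrade_suggested  # very large domain
    # exactly at the ratio boundary: 5/10 is not > 0.5
    a, _ = assign_pm1(
        bundle(
            domain=DomainContext(
                in_domain=True, domain_length_aa=100,
                n_pathogenic_in_domain=5, n_benign_in_domain=5,
            )
        )
    )
    assert a is None
    # 6/11 > 0.5, 11 variants in a small domain → no downgrade suggestion
    a, _ = assign_pm1(
        bundle(
            domain=DomainContext(
                in_domain=True, domain_length_aa=100,
                n_pathogenic_in_domain=6, n_benign_in_domain=5,
            )
        )
    )
    assert a is not None and not a.downgrade_suggested


def test_pm1_zero_denominator_does_not_trigger_domain_branch():
    a, _ = assign_pm1(bundle(domain=DomainContext(in_domain=True)))
    assert a is None


def test_pm1_withheld_for_disulfide_bond_annotation_off_residue():
    dom = DomainContext(
        in_domain=True, domain_name="disulfide bond_30-118", domain_length_aa=89,
        n_pathogenic_in_domain=6, n_benign_in_domain=0,
        is_disulfide_bond_annotation=True, variant_at_bond_residue=False,
    )
    a, excluded = assign_pm1(bundle(domain=dom))
    assert a is None and any(c is C.PM1 for c, _ in excluded)
    # at a bond residue the domain evidence counts again
    a, _ = assign_pm1(
        bundle(domain=dom.model_copy(update={"variant_at_bond_residue": True}))
    )
    assert a is not None


def test_pm1_domain_downgrade_when_fewer_than_10_variants():
    a, _ = assign_pm1(
        bundle(
            domain=DomainContext(
                in_domain=True, domain_length_aa=57,
                n_pathogenic_in_domain=4, n_benign_in_domain=1,
            )
        )
    )
    assert a is not None and a.downgrade_suggested


# ------------------------------------------------------------------ run_auto


def test_run_auto_empty_bundle():
    report = run_auto(bundle())
    assert report.assignments == []
    assert report.decision_maf == 0.0


def test_run_auto_clamps_external_benign_boost():
    b = bundle(
        clinical_db={"clinvar_interpretation": "none"},
        externally_supplied_criteria=[
            CriterionAssignment(
                code=C.BP6, strength=StrengthLevel.VERY_STRONG, source="external"
            )
        ],
    )
    report = run_auto(b)
    bp6 = next(a for a in report.assignments if a.code is C.BP6)
    assert bp6.strength is StrengthLevel.SUPPORTING


def test_run_auto_clinvar_zero_stars_excludes_pp5():
    b = bundle(
        clinical_db={
            "clinvar_interpretation": "pathogenic",
            "clinvar_review_stars": 0,
            "other_db_submissions": False,
        }
    )
    report = run_auto(b)
    assert C.PP5 not in report.assigned_codes
    assert any(c is C.PP5 and "0 stars" in r for c, r in report.excluded)
    # a submission elsewhere rescues the criterion
    b2 = bundle(
        clinical_db={
            "clinvar_interpretation": "pathogenic",
            "clinvar_review_stars": 0,
            "other_db_submissions": True,
        }
    )
    assert C.PP5 in run_auto(b2).assigned_codes


def test_run_auto_pm4_gating():
    stop_loss = bundle(transcript=TranscriptContext(consequence="stop_loss"))
    assert C.PM4 in run_auto(stop_loss).assigned_codes
    repeat = bundle(
        transcript=TranscriptContext(
            consequence="inframe_indel", in_repeat_region_no_function=True
        )
    )
    report = run_auto(repeat)
    assert C.BP3 in report.assigned_codes and C.PM4 not in report.assigned_codes


def test_run_auto_ps1_strength_depends_on_alternative_classification():
    strong = bundle(
        transcript=TranscriptContext(
            consequence="missense",
            same_aa_change_as_pathogenic=True,
            alt_variant_at_residue_classification="pathogenic",
        )
    )
    a = next(x for x in run_auto(strong).assignments if x.code is C.PS1)
    assert a.strength is StrengthLevel.STRONG
    lp = bundle(
        transcript=TranscriptContext(
            consequence="missense",
            same_aa_change_as_pathogenic=True,
            alt_variant_at_residue_classification="likely_pathogenic",
        )
    )
    a = next(x for x in run_auto(lp).assignments if x.code is C.PS1)
    assert a.strength is StrengthLevel.SUPPORTING


def test_run_auto_bp7_for_silent_variant_without_splice_impact():
    silent = bundle(transcript=TranscriptContext(consequence="synonymous"))
    assert C.BP7 in run_auto(silent).assigned_codes
    spliceogenic = bundle(
        transcript=TranscriptContext(consequence="synonymous"),
        predictors=PredictorPanel(ada_score=0.9, rf_score=0.9),
    )
    assert C.BP7 not in run_auto(spliceogenic).assigned_codes


# --------------------------------------------------- properties / invariants


@st.composite
def random_bundles(draw):
    from acmgkit.simulate import SUPPORTED_TARGETS, ScenarioSpec, infeasibility_reason, make_bundle

    codes = sorted(SUPPORTED_TARGETS, key=lambda c: c.value)
    targets = set(draw(st.lists(st.sampled_from(codes), max_size=3, unique=True)))
    if infeasibility_reason(targets):
        targets = set()
    seed = draw(st.integers(0, 2**31 - 1))
    return make_bundle(ScenarioSpec(target_criteria=targets, jitter=True, seed=seed))


@settings(max_examples=300, derandomize=True, deadline=None)
@given(random_bundles())
def test_mutual_exclusion_invariants_hold(b):
    report = run_auto(b)  # AutoAssignmentReport validates exclusions on build
    assigned = report.assigned_codes
    for x, y in MUTUALLY_EXCLUSIVE_PAIRS:
        assert not (x in assigned and y in assigned)
    assert not assigned & {c for c, _ in report.excluded}


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 20), st.integers(0, 20))
def test_pm2_monotone_in_allele_count(ac_low, delta):
    """Increasing allele_count never turns PM2 from absent to present."""
    lo = freq_codes(freq_bundle({"AD"}, ac=ac_low))
    hi = freq_codes(freq_bundle({"AD"}, ac=ac_low + delta))
    if C.PM2 not in lo:
        assert C.PM2 not in hi


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10), st.integers(0, 10))
def test_pp3_monotone_in_concordant_pathogenic_calls(npath, extra):
    """Adding concordant pathogenic predictor calls never removes PP3."""
    lo = pred_codes(pred_bundle(npath, 0))
    hi = pred_codes(pred_bundle(npath + extra, 0))
    if C.PP3 in lo:
        assert C.PP3 in hi


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.floats(0.0, 1.0, allow_nan=False), st.integers(0, 2**31 - 1))
def test_allowlisted_variant_never_gets_ba1(maf, seed):
    b = bundle(
        variant_id="NM_000372(TYR):c.1205G>A",
        gene_context=GeneContext(gene="TYR", inheritance={"AR"}),
        population=PopulationRecord(
            subpop_frequencies={"NFE": maf}, allele_count=seed % 1000
        ),
    )
    assert C.BA1 not in run_auto(b).assigned_codes
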