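"""Reviewer checklist: adjustment validation, manual-criteria grading, atomicity."""

import pytest

from acmgkit import (
    Adjustment,
    ChecklistPolicy,
    CriterionCode,
    GeneContext,
    StrengthLevel,
    Verdict,
    apply_adjustments,
    classify_with_audit,
    grade_pm3,
    grade_pp1,
    grade_pp4,
    grade_ps4,
    validate_adjustment,
)
from acmgkit.review import MANUAL_ONLY_CODES, AdjustmentError

C = CriterionCode
S = StrengthLevel


def adj(code, action, strength=None, why="checklist-backed adjustment"):
    return Adjustment(
        code=C(code), action=action, new_strength=strength, justification=why
    )


# ------------------------------------------------------------------- policy


def test_manual_only_codes_match_unautomatable_criteria():
    assert MANUAL_ONLY_CODES == {
        C.BS3, C.BS4, C.BP2, C.BP5, C.PS2, C.PS3, C.PS4, C.PM3, C.PM6, C.PP1, C.PP4,
    }


@pytest.mark.parametrize(
    "code,strength,ok",
    [
        ("PM1", S.SUPPORTING, True),   # <10 variants in domain → downgrade
        ("PM1", S.STRONG, False),      # checklist caps PM1 at Moderate
        ("BS1", S.MODERATE, False),    # benign never Moderate
        ("BP6", S.VERY_STRONG, False),
        ("PM3", S.STRONG, True),       # multiple trans partners → upgrade
        ("PP1", S.STRONG, True),
        ("PP4", S.MODERATE, True),     # single-gene disorder
        ("PP4", S.STRONG, False),
        ("PS1", S.SUPPORTING, True),   # LP alternative variant
        ("BP2", S.STRONG, True),       # confirmed in many individuals
        ("PVS1", S.MODERATE, True),
    ],
)
def test_validate_adjustment_against_checklist_ranges(code, strength, ok):
    valid, _ = validate_adjustment(adj(code, "set_strength", strength))
    assert valid is ok


def test_bs1_standalone_requires_high_penetrance_context():
    a = adj("BS1", "set_strength", S.STAND_ALONE)
    ok, reason = validate_adjustment(a)
    assert not ok and "penetrance" in reason
    ok, _ = validate_adjustment(
        a, gene_context=GeneContext(gene="G", inheritance={"AD"}, high_penetrance=True)
    )
    assert ok


def test_policy_rejects_benign_moderate_in_allowed_strengths():
    with pytest.raises(ValueError):
        ChecklistPolicy(allowed_strengths={C.BS2: {S.MODERATE}})


# ------------------------------------------------------------------ grading


@pytest.mark.parametrize(
    "n,expected",
    [(1, S.SUPPORTING), (2, S.MODERATE), (3, S.MODERATE), (4, S.STRONG), (9, S.STRONG)],
)
def test_grade_pp1_cosegregation_breakpoints(n, expected):
    assert grade_pp1(n) is expected


def test_grade_pp1_rejects_zero_affected():
    with pytest.raises(ValueError):
        grade_pp1(0)


@pytest.mark.parametrize(
    "n_trans,homozygous,multi,expected",
    [
        (0, False, False, None),
        (1, False, False, S.SUPPORTING),
        (0, True, False, S.SUPPORTING),
        (3, False, True, S.STRONG),
        (2, False, False, S.STRONG),
        (1, False, True, S.STRONG),
    ],
)
def test_grade_pm3_in_trans_evidence(n_trans, homozygous, multi, expected):
    assert grade_pm3(n_trans, homozygous, multi) is expected


@pytest.mark.parametrize(
    "count,single,expected",
    [
        (1, True, S.MODERATE),   # true single-gene disorder
        (5, False, S.SUPPORTING),
        (6, False, None),
        (2, False, S.SUPPORTING),
    ],
)
def test_grade_pp4_phenotype_specificity(count, single, expected):
    assert grade_pp4(count, single) is expected


@pytest.mark.parametrize(
    "n,case_control,expected",
    [(5, False, S.STRONG), (4, False, None), (0, True, S.STRONG)],
)
def test_grade_ps4_prevalence(n, case_control, expected):
    assert grade_ps4(n, case_control) is expected


def test_grading_breakpoint_recovery():
    """Monotone probes over the integer arguments recover the printed
    breakpoints: 1/2/4 for co-segregation, 5 for prevalence and
    phenotype gene count."""
    pp1 = [grade_pp1(n) for n in range(1, 10)]
    assert pp1[:1] == [S.SUPPORTING] and pp1[1:3] == [S.MODERATE] * 2
    assert all(s is S.STRONG for s in pp1[3:])
    ps4 = [grade_ps4(n) for n in range(0, 10)]
    assert ps4[:5] == [None] * 5 and all(s is S.STRONG for s in ps4[5:])
    pp4 = [grade_pp4(n) for n in range(1, 10)]
    assert all(s is S.SUPPORTING for s in pp4[:5]) and all(s is None for s in pp4[5:])


# ------------------------------------------------------------- apply batch


def base_result(factory, *tokens):
    return classify_with_audit([factory(t) for t in tokens], variant_id="V1")


def test_empty_adjustment_list_is_identity(assignment_factory):
    result = base_result(assignment_factory, "PM1", "PM2", "PP3")
    after = apply_adjustments(result, [])
    assert after.verdict is result.verdict
    assert after.active_codes == result.active_codes


def test_downgrade_pvs1_and_remove_pp3_yields_vus(assignment_factory):
    result = base_result(assignment_factory, "PVS1@VeryStrong", "PM2", "PP3")
    assert result.verdict is Verdict.PATHOGENIC
    after = apply_adjustments(
        result,
        [adj("PVS1", "set_strength", S.MODERATE), adj("PP3", "remove")],
    )
    assert after.verdict is Verdict.UNCERTAIN
    assert after.active_codes == {C.PVS1, C.PM2}
    assert after.auto_verdict is Verdict.PATHOGENIC


def test_add_manual_criterion_reclassifies(assignment_factory):
    result = base_result(assignment_factory, "PM2", "PP3")
    after = apply_adjustments(
        result, [adj("PP1", "add", S.SUPPORTING), adj("PP4", "add", S.SUPPORTING)]
    )
    # 1 Moderate + 3 Supporting → Likely Pathogenic (modified rule)
    assert after.verdict is Verdict.LIKELY_PATHOGENIC


def test_atomicity_one_invalid_adjustment_rejects_batch(assignment_factory):
    result = base_result(assignment_factory, "PM1", "PM2")
    with pytest.raises(AdjustmentError):
        apply_adjustments(
            result,
            [adj("PM1", "set_strength", S.SUPPORTING), adj("PM1", "set_strength", S.STRONG)],
        )
    # original untouched
    assert result.active_codes == {C.PM1, C.PM2}


def test_remove_inactive_criterion_rejected(assignment_factory):
    result = base_result(assignment_factory, "PM2")
    with pytest.raises(AdjustmentError, match="not active"):
        apply_adjustments(result, [adj("PP3", "remove")])


def test_adjustments_recorded_in_audit_with_justification(assignment_factory):
    result = base_result(assignment_factory, "PM1", "PM2")
    after = apply_adjustments(
        result, [adj("PM1", "set_strength", S.SUPPORTING, why="small domain")]
    )
    assert any("small domain" in line for line in after.audit)
    assert len(after.adjustments_applied) == 1


def test_policy_closure_no_valid_sequence_boosts_benign(assignment_factory):
    """No sequence of valid adjustments can put a benign criterion at
    Moderate or VeryStrong."""
    result = base_result(assignment_factory, "BS2", "BP4")
    for strength in (S.MODERATE, S.VERY_STRONG):
        for code in ("BS2", "BP4", "BP6"):
            ok, _ = validate_adjustment(adj(code, "set_strength", strength))
            assert not ok
    # and applying a valid benign sequence keeps legal strengths
    after = apply_adjustments(
        result, [adj("BP4", "set_strength", S.STRONG, why="strong concordance")]
    )
    for a in after.active_assignments:
        if a.code.is_benign:
            assert a.strength in (S.SUPPORTING, S.STRONG, S.STAND_ALONE)
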