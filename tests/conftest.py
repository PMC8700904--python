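import pytest

from acmgkit import CriterionAssignment, CriterionCode, StrengthLevel, default_strength


@pytest.fixture
def assignment_factory():
    """Build a CriterionAssignment from a 'CODE' or 'CODE@Strength' token."""

    def make(token: str, **kw) -> CriterionAssignment:
        code_s, _, strength_s = token.partition("@")
        code = CriterionCode(code_s)
        strength = (
            {
                "Supporting": StrengthLevel.SUPPORTING,
                "Moderate": StrengthLevel.MODERATE,
                "Strong": StrengthLevel.STRONG,
                "VeryStrong": StrengthLevel.VERY_STRONG,
                "StandAlone": StrengthLevel.STAND_ALONE,
            }[strength_s]
            if strength_s
            else default_strength(code)
        )
        return CriterionAssignment(code=code, strength=strength, **kw)

    return make
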