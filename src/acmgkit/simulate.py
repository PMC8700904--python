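"""Seeded synthetic-evidence generator.

Builds EvidenceBundles that trigger exactly a requested set of
automatically assignable criteria, by construction: each criterion's
decisive inputs are set just inside its printed threshold and every
other input is held just outside (or jittered within the safe range
when ``jitter`` is on). This makes every engine rule testable without
any database download.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import (
    ClinicalDbContext,
    CriterionCode,
    DomainContext,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    PredictorPanel,
    TranscriptContext,
)

#: auto-assignable codes the generator can target
SUPPORTED_TARGETS = frozenset(
    {
        CriterionCode.PVS1,
        CriterionCode.PS1,
        CriterionCode.PM1,
        CriterionCode.PM2,
        CriterionCode.PM4,
        CriterionCode.PM5,
        CriterionCode.BA1,
        CriterionCode.BS2,
        CriterionCode.PP2,
        CriterionCode.PP3,
        CriterionCode.PP5,
        CriterionCode.BP1,
        CriterionCode.BP3,
        CriterionCode.BP4,
        CriterionCode.BP6,
        CriterionCode.BP7,
    }
)

# pairs that can never co-occur in one auto report
_INFEASIBLE_PAIRS = frozenset(
    {
        frozenset({CriterionCode.PP3, CriterionCode.BP4}),
        frozenset({CriterionCode.BP1, CriterionCode.PP2}),
        frozenset({CriterionCode.PM2, CriterionCode.BS2}),
        frozenset({CriterionCode.BA1, CriterionCode.BS2}),
        frozenset({CriterionCode.PS1, CriterionCode.PM5}),
        frozenset({CriterionCode.PVS1, CriterionCode.PP3}),
        frozenset({CriterionCode.PVS1, CriterionCode.BP4}),
        frozenset({CriterionCode.PVS1, CriterionCode.PM4}),
        frozenset({CriterionCode.PP5, CriterionCode.BP6}),
    }
)

# codes pinned to a transcript consequence
_REQUIRED_CONSEQUENCE = {
    CriterionCode.PVS1: "nonsense",
    CriterionCode.PM4: "inframe_indel",
    CriterionCode.BP3: "inframe_indel",
    CriterionCode.BP7: "synonymous",
    CriterionCode.PP2: "missense",
    CriterionCode.BP1: "missense",
    CriterionCode.PM5: "missense",
    CriterionCode.PS1: "missense",
}


class ScenarioSpec(BaseModel):
    """A target set of auto criteria plus generation controls."""

    target_criteria: set[CriterionCode] = Field(default_factory=set)
    jitter: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "ScenarioSpec":
        problem = infeasibility_reason(self.target_criteria)
        if problem:
            raise ValueError(problem)
        return self


def infeasibility_reason(targets: set[CriterionCode]) -> str | None:
    """None if the target set is constructible, else why not."""
    unsupported = targets - SUPPORTED_TARGETS
    if unsupported:
        return (
            "unsupported target criteria: "
            + ", ".join(sorted(c.value for c in unsupported))
        )
    for pair in _INFEASIBLE_PAIRS:
        if pair <= targets:
            a, b = sorted(c.value for c in pair)
            return f"mutually exclusive targets: {a}/{b}"
    consequences = {
        _REQUIRED_CONSEQUENCE[c] for c in targets if c in _REQUIRED_CONSEQUENCE
    }
    if len(consequences) > 1:
        return "targets require conflicting transcript consequences: " + ", ".join(
            sorted(consequences)
        )
    # PM4 requires an in-frame consequence, which is itself what fires PM4:
    # BP3 pins the repeat flag the other way
    if CriterionCode.PM4 in targets and CriterionCode.BP3 in targets:
        return "mutually exclusive targets: BP3/PM4"
    return None


def make_bundle(spec: ScenarioSpec) -> EvidenceBundle:
    """Construct a bundle on which run_auto triggers exactly
    ``spec.target_criteria`` (among auto-assignable codes)."""
    targets = spec.target_criteria
    rng = np.random.default_rng(spec.seed)
    C = CriterionCode

    consequence = "other"
    for code in targets:
        if code in _REQUIRED_CONSEQUENCE:
            consequence = _REQUIRED_CONSEQUENCE[code]
    if consequence == "other" and (C.PP3 in targets or C.BP4 in targets):
        consequence = "missense"

    def jit(lo: int, hi: int, default: int) -> int:
        return int(rng.integers(lo, hi + 1)) if spec.jitter else default

    gene = f"GENE{jit(1, 999, 1)}"
    gc = GeneContext(
        gene=gene,
        inheritance={"AD"},
        # late-onset disables BS2 so the neutral base (allele_count at the
        # PM2 cutoff) triggers no frequency criterion at all
        late_onset=C.BS2 not in targets,
        phenotype_gene_count=jit(2, 20, 6),
        lof_mechanism=C.PVS1 in targets,
        low_benign_missense_rate=C.PP2 in targets,
        truncating_mechanism=C.BP1 in targets,
    )

    freqs: dict[str, float] = {}
    if C.BA1 in targets:
        freqs["NFE"] = 0.051  # just above the 5% stand-alone cutoff
    else:
        freqs["NFE"] = round(float(rng.uniform(0, 0.02)), 6) if spec.jitter else 0.0
    # excluded founder subpopulations never influence DecisionMAF
    if spec.jitter:
        freqs["FIN"] = round(float(rng.uniform(0, 0.9)), 6)
    pop = PopulationRecord(
        subpop_frequencies=freqs,
        allele_count=4 if C.PM2 in targets else 5,
        homozygote_count=jit(0, 2, 0),
        hemizygote_count=jit(0, 2, 0),
    )

    panel = PredictorPanel(
        n_pathogenic_calls=3 if C.PP3 in targets else 0,
        n_benign_calls=3 if C.BP4 in targets else 0,
    )

    if C.PM1 in targets:
        dom = DomainContext(
            pathogenic_neighbor_distances_nt=[25] * 6  # just inside the window
        )
    else:
        # neighbors strictly outside the 25-nt window are inert
        extra = (
            [int(rng.integers(26, 500)) for _ in range(int(rng.integers(0, 6)))]
            if spec.jitter
            else []
        )
        dom = DomainContext(pathogenic_neighbor_distances_nt=extra)

    tx = TranscriptContext(
        consequence=consequence,  # type: ignore[arg-type]
        in_repeat_region_no_function=C.BP3 in targets,
        same_aa_change_as_pathogenic=C.PS1 in targets,
        alt_variant_at_residue_classification=(
            "pathogenic" if (C.PM5 in targets or C.PS1 in targets) else "none"
        ),
    )

    if C.PP5 in targets:
        db = ClinicalDbContext(
            clinvar_interpretation="pathogenic", clinvar_review_stars=jit(1, 4, 2)
        )
    elif C.BP6 in targets:
        db = ClinicalDbContext(
            clinvar_interpretation="benign", clinvar_review_stars=jit(1, 4, 2)
        )
    else:
        db = ClinicalDbContext()

    label = "+".join(sorted(c.value for c in targets)) or "none"
    return EvidenceBundle(
        variant_id=f"SYN:{spec.seed}:{label}",
        gene_context=gc,
        population=pop,
        predictors=panel,
        domain=dom,
        transcript=tx,
        clinical_db=db,
    )


def random_scenarios(n: int, seed: int = 0, jitter: bool = True) -> list[ScenarioSpec]:
    """n feasible random scenario specs (rejection sampling)."""
    rng = np.random.default_rng(seed)
    codes = sorted(SUPPORTED_TARGETS, key=lambda c: c.value)
    out: list[ScenarioSpec] = []
    while len(out) < n:
        k = int(rng.integers(0, 4))
        picked = set(rng.choice(len(codes), size=k, replace=False).tolist())
        targets = {codes[i] for i in picked}
        if infeasibility_reason(targets):
            continue
        out.append(
            ScenarioSpec(
                target_criteria=targets,
                jitter=jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out
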