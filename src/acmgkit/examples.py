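"""Canned evidence bundles reproducing published case studies.

Each worked example packages the pre-annotated evidence for one variant
discussed in the source case series (RIT1, DSP, CTSC, ABCA4, CRB1,
PIEZO1, TYR), the expected automatic criteria and verdict, and — where
the case involved curation — the reviewer adjustments with the expected
final verdict. Criteria compositions not fully published are
partially specified: only the printed facts are asserted
(``expected_codes_subset`` / ``absent_codes``).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field

from .model import (
    Adjustment,
    ClinicalDbContext,
    CriterionAssignment,
    CriterionCode,
    DomainContext,
    EvidenceBundle,
    GeneContext,
    PopulationRecord,
    PredictorPanel,
    StrengthLevel,
    TranscriptContext,
    Verdict,
)

C = CriterionCode
S = StrengthLevel


class WorkedExample(BaseModel):
    name: str
    bundle: EvidenceBundle
    inheritance_override: Optional[str] = None
    expected_auto_codes: Optional[set[CriterionCode]] = None  # exact, when published
    expected_codes_subset: set[CriterionCode] = Field(default_factory=set)
    absent_codes: set[CriterionCode] = Field(default_factory=set)
    expected_auto_verdict: Optional[Verdict] = None
    expected_pvs1_strength: Optional[StrengthLevel] = None
    adjustments: list[Adjustment] = Field(default_factory=list)
    expected_final_verdict: Optional[Verdict] = None
    expect_phenotype_modifier: bool = False


def paper_worked_examples() -> list[WorkedExample]:
    """The published case-study fixtures with their expected outcomes."""
    examples: list[WorkedExample] = []

    # RIT1 c.650C>G p.(Ser217*): nonsense in a Noonan-syndrome gene.
    # Automated: PVS1 at VeryStrong + PM2 + upstream PP3 → Pathogenic.
    # Curation: the LoF decision tree grades PVS1 Moderate (NMD path) and
    # PP3 is disabled for LoF variants → UncertainSignificance.
    examples.append(
        WorkedExample(
            name="RIT1:c.650C>G",
            bundle=EvidenceBundle(
                variant_id="NM_006912(RIT1):c.650C>G",
                gene_context=GeneContext(
                    gene="RIT1", inheritance={"AD"}, lof_mechanism=True
                ),
                population=PopulationRecord(allele_count=0),
                transcript=TranscriptContext(consequence="nonsense"),
                # upstream annotator assigned PP3 despite PVS1
                # (the engine itself withholds it)
                externally_supplied_criteria=[
                    CriterionAssignment(
                        code=C.PP3, strength=S.SUPPORTING, source="external"
                    )
                ],
            ),
            expected_auto_codes={C.PVS1, C.PM2, C.PP3},
            expected_auto_verdict=Verdict.PATHOGENIC,
            expected_pvs1_strength=S.VERY_STRONG,
            adjustments=[
                Adjustment(
                    code=C.PVS1,
                    action="set_strength",
                    new_strength=S.MODERATE,
                    justification="LoF decision tree grades PVS1 Moderate (NMD-escape path)",
                ),
                Adjustment(
                    code=C.PP3,
                    action="remove",
                    justification="in-silico criteria disabled for LoF variants",
                ),
            ],
            expected_final_verdict=Verdict.UNCERTAIN,
        )
    )

    # DSP c.2582C>T p.(Thr861Ile): VUS with PM1 + PM2 + BP4; PM1 comes
    # from the 1056-aa "Globular 1" domain with 15 pathogenic / 8 benign
    # classified variants, so a downgrade to Supporting is suggested —
    # without changing the verdict.
    examples.append(
        WorkedExample(
            name="DSP:c.2582C>T",
            bundle=EvidenceBundle(
                variant_id="NM_004415(DSP):c.2582C>T",
                gene_context=GeneContext(gene="DSP", inheritance={"AD"}),
                population=PopulationRecord(allele_count=1),
                predictors=PredictorPanel(n_benign_calls=4),
                domain=DomainContext(
                    in_domain=True,
                    domain_name="Globular 1",
                    domain_length_aa=1056,
                    n_pathogenic_in_domain=15,
                    n_benign_in_domain=8,
                ),
                transcript=TranscriptContext(consequence="missense"),
            ),
            expected_auto_codes={C.PM1, C.PM2, C.BP4},
            expected_auto_verdict=Verdict.UNCERTAIN,
            adjustments=[
                Adjustment(
                    code=C.PM1,
                    action="set_strength",
                    new_strength=S.SUPPORTING,
                    justification="23 classified variants scattered in a very "
                    "large (1056 aa) domain",
                ),
            ],
            expected_final_verdict=Verdict.UNCERTAIN,
        )
    )

    # CTSC c.151G>T p.(Asp51Tyr): located in "disulfide bond_30-118";
    # the bond involves only the bridge cysteines → PM1 withheld.
    examples.append(
        WorkedExample(
            name="CTSC:c.151G>T",
            bundle=EvidenceBundle(
                variant_id="NM_001814(CTSC):c.151G>T",
                gene_context=GeneContext(gene="CTSC", inheritance={"AR"}),
                population=PopulationRecord(homozygote_count=0),
                domain=DomainContext(
                    in_domain=True,
                    domain_name="disulfide bond_30-118",
                    domain_length_aa=89,
                    n_pathogenic_in_domain=4,
                    n_benign_in_domain=1,
                    is_disulfide_bond_annotation=True,
                    variant_at_bond_residue=False,
                ),
                transcript=TranscriptContext(consequence="missense"),
            ),
            absent_codes={C.PM1},
        )
    )

    # ABCA4 c.514G>A p.(Gly172Ser): "disulfide bond_75-324", same rule.
    examples.append(
        WorkedExample(
            name="ABCA4:c.514G>A",
            bundle=EvidenceBundle(
                variant_id="NM_000350(ABCA4):c.514G>A",
                gene_context=GeneContext(gene="ABCA4", inheritance={"AR"}),
                population=PopulationRecord(homozygote_count=0),
                domain=DomainContext(
                    in_domain=True,
                    domain_name="disulfide bond_75-324",
                    domain_length_aa=250,
                    n_pathogenic_in_domain=3,
                    n_benign_in_domain=0,
                    is_disulfide_bond_annotation=True,
                    variant_at_bond_residue=False,
                ),
                transcript=TranscriptContext(consequence="missense"),
            ),
            absent_codes={C.PM1},
        )
    )

    # CRB1 c.1024_1032del p.(Glu342_Asn344del): in-frame deletion in the
    # 57-aa "EGF-like 9" domain, 4 pathogenic vs 1 benign → PM1 assigned;
    # fewer than 10 classified variants, so the downgrade is suggested
    # (the curator kept Moderate: the deletion removes a bond cysteine).
    examples.append(
        WorkedExample(
            name="CRB1:c.1024_1032del",
            bundle=EvidenceBundle(
                variant_id="NM_201253(CRB1):c.1024_1032del",
                gene_context=GeneContext(gene="CRB1", inheritance={"AR"}),
                population=PopulationRecord(homozygote_count=0),
                domain=DomainContext(
                    in_domain=True,
                    domain_name="EGF-like 9",
                    domain_length_aa=57,
                    n_pathogenic_in_domain=4,
                    n_benign_in_domain=1,
                ),
                transcript=TranscriptContext(consequence="inframe_indel"),
            ),
            expected_codes_subset={C.PM1},
        )
    )

    # PIEZO1 c.1447G>A p.(Val483Met): dominant per the curated gene-disease
    # database → BS2 from 13 gnomAD alleles → LikelyBenign; under the
    # recessive override (0 homozygotes) PM2 applies instead → VUS.
    examples.append(
        WorkedExample(
            name="PIEZO1:c.1447G>A[AD]",
            bundle=_piezo1_1447(),
            expected_codes_subset={C.BS2},
            expected_auto_verdict=Verdict.LIKELY_BENIGN,
        )
    )
    examples.append(
        WorkedExample(
            name="PIEZO1:c.1447G>A[AR-override]",
            bundle=_piezo1_1447(),
            inheritance_override="AR",
            expected_codes_subset={C.PM2},
            absent_codes={C.BS2},
            expected_auto_verdict=Verdict.UNCERTAIN,
        )
    )

    # PIEZO1 c.5891T>C p.(Met1964Thr): one gnomAD allele → PM2; predictors
    # split 7 pathogenic vs 5 benign, below the concordance bar → VUS.
    examples.append(
        WorkedExample(
            name="PIEZO1:c.5891T>C",
            bundle=EvidenceBundle(
                variant_id="NM_001142864(PIEZO1):c.5891T>C",
                gene_context=GeneContext(gene="PIEZO1", inheritance={"AD"}),
                population=PopulationRecord(allele_count=1),
                predictors=PredictorPanel(n_pathogenic_calls=7, n_benign_calls=5),
                transcript=TranscriptContext(consequence="missense"),
            ),
            expected_codes_subset={C.PM2},
            expected_auto_verdict=Verdict.UNCERTAIN,
        )
    )

    # ABCA4 c.5603A>T p.(Asn1868Ile): ~7% in Europeans yet hypomorphic;
    # exempt from BA1 and carried through as a phenotype modifier.
    examples.append(
        WorkedExample(
            name="ABCA4:c.5603A>T",
            bundle=EvidenceBundle(
                variant_id="NM_000350(ABCA4):c.5603A>T",
                gene_context=GeneContext(gene="ABCA4", inheritance={"AR"}),
                population=PopulationRecord(
                    subpop_frequencies={"NFE": 0.07},
                    allele_count=18000,
                    homozygote_count=700,
                ),
                transcript=TranscriptContext(consequence="missense"),
            ),
            absent_codes={C.BA1},
            expect_phenotype_modifier=True,
        )
    )

    # TYR c.1205G>A p.(Arg402Gln): ~27% in non-Finnish Europeans;
    # thermosensitive hypomorph, same exemption.
    examples.append(
        WorkedExample(
            name="TYR:c.1205G>A",
            bundle=EvidenceBundle(
                variant_id="NM_000372(TYR):c.1205G>A",
                gene_context=GeneContext(gene="TYR", inheritance={"AR"}),
                population=PopulationRecord(
                    subpop_frequencies={"NFE": 0.27},
                    allele_count=70000,
                    homozygote_count=9000,
                ),
                transcript=TranscriptContext(consequence="missense"),
            ),
            absent_codes={C.BA1},
            expect_phenotype_modifier=True,
        )
    )

    return examples


def _piezo1_1447() -> EvidenceBundle:
    return EvidenceBundle(
        variant_id="NM_001142864(PIEZO1):c.1447G>A",
        gene_context=GeneContext(gene="PIEZO1", inheritance={"AD"}),
        population=PopulationRecord(allele_count=13, homozygote_count=0),
        transcript=TranscriptContext(consequence="missense"),
    )
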