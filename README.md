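# acmgkit

A rules engine for clinical sequence-variant interpretation under the
ACMG/AMP framework, with the modifications a diagnostic laboratory
applies on top of automated annotation: inheritance-aware population
cutoffs, loss-of-function strength grading, hotspot/domain scoring with
the disulfide-bond exception, hypomorphic-variant exemptions from the
stand-alone frequency rule, a reviewer-adjustment checklist, and
primary/secondary clinical-report tiering.

It is written for molecular geneticists and bioinformaticians who
receive **pre-annotated** variant evidence (gnomAD-style population
counts, in-silico predictor calls, domain statistics, ClinVar review
status) and need a reproducible, auditable path from that evidence to a
five-tier verdict.

## The model

Each variant is scored against the 28 ACMG/AMP evidence criteria — 16
pathogenic (PVS1, PS1–PS4, PM1–PM6, PP1–PP5) and 12 benign (BA1,
BS1–BS4, BP1–BP7) — each carried at an effective strength
(Supporting < Moderate < Strong < VeryStrong; StandAlone for BA1).
Criteria are counted per effective strength bucket
(PVS, PS, PM, PP / BA, BS, BP) and combined:

* **Pathogenic**: 1 PVS + (≥1 PS | ≥2 PM | 1 PM + ≥1 PP | ≥2 PP | a
  second PVS); or ≥2 PS; or 1 PS + (≥3 PM | 2 PM + ≥2 PP | 1 PM + ≥4 PP)
* **Likely pathogenic**: 1 PVS + 1 PM; 1 PS + 1–2 PM; 1 PS + ≥2 PP;
  ≥3 PM; 2 PM + ≥2 PP; **1 PM + ≥3 PP**
* **Benign**: BA1, or ≥2 BS — **Likely benign**: 1 BS, or ≥2 BP
* contradictory pathogenic + benign evidence → uncertain significance
  (VUS)

Laboratory modifications (bold above, plus): 1 PVS + 1 PM + ≥1 PP
reaches Pathogenic; two VeryStrong criteria reach Pathogenic; 1 PM +
3 PP reaches Likely pathogenic (only three of the five PP rules can be
automated); a *single* Strong benign criterion co-occurring with any
pathogenic criterion is suppressed; benign criteria are clamped back to
Supporting/Strong if an upstream annotator boosted them.

Automatic assignment uses the documented cutoffs: DecisionMAF (maximum
subpopulation frequency excluding Finnish/Ashkenazi/other) < 3% to
select variants, BA1 above 5%, PM2 below 5 gnomAD alleles (dominant or
mixed models) or below 3 homozygotes/hemizygotes (recessive/X-linked),
BS2 at or above the same cutoffs, PM1 from ≥6 pathogenic neighbors
within 25 coding bases or a domain pathogenic ratio > 0.5, PP3/BP4 from
≥3 concordant predictors or dbscSNV splice scores (ADA > 0.708,
RF > 0.515) for intronic variants.

## Worked example

A nonsense variant in *RIT1* (Noonan syndrome, autosomal dominant,
loss-of-function mechanism), absent from gnomAD, with an upstream
annotator's PP3 call supplied alongside the evidence:

```python
import acmgkit as ak
from acmgkit.examples import paper_worked_examples

ex = next(e for e in paper_worked_examples() if e.name == "RIT1:c.650C>G")

auto = ak.classify_bundle(ex.bundle)
print(auto.verdict.value, auto.matched_clause)
# Pathogenic Pathogenic(i.c)   — PVS1@VeryStrong + PM2@Moderate + PP3@Supporting

final = ak.review_bundle(ex.bundle, ex.adjustments)
print(final.verdict.value, sorted(a.code.value for a in final.active_assignments))
# UncertainSignificance ['PM2', 'PVS1']
for line in final.audit:
    print(line)
# reviewer set_strength PVS1 -> Moderate: LoF decision tree grades PVS1 Moderate (NMD-escape path)
# reviewer remove PP3: in-silico criteria disabled for LoF variants
```

The automatic verdict is Pathogenic via the modified clause
1 VeryStrong + 1 Moderate + 1 Supporting. After curation — the LoF
decision tree grades PVS1 only Moderate for this transcript position,
and in-silico criteria are not used for LoF variants — the effective
tally is two Moderates, which meets no clause: the variant is reported
as a VUS in the Primary tier.

The same flows are available from the shell:

```bash
acmgkit simulate --out evidence.tsv --n 20 --seed 1
acmgkit classify --evidence evidence.tsv --out report.tsv
acmgkit review --evidence evidence.tsv --adjustments adj.tsv --out final.tsv
acmgkit audit-rules --out rules.tsv       # exhaustive combination-table dump
acmgkit --print-config                    # all thresholds and allowlists
```

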