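# Methods

## Scope and data flow

`acmgkit` classifies single variants from *pre-annotated* evidence: it
performs no alignment, no variant calling, no database queries, and no
HGVS parsing (variant identifiers are opaque labels). One
`EvidenceBundle` per variant carries six sub-records — gene context,
population counts, predictor panel, domain statistics, transcript
flags, and a clinical-database summary — plus any criteria an upstream
annotator already assigned. Absent evidence always means "no criterion
triggered", never an error, because real annotation is sparse.

The pipeline is: automatic criterion assignment (`engine`), criterion
combination into the five-tier verdict (`combine` + `table1`),
optional reviewer adjustments (`review`), and report tiering/filtering
(`io`). Every stage leaves an audit record: exclusions carry
machine-readable reasons, suppressions and clamps are logged, and
reviewer actions keep their justifications.

## Automatic rules and their parameters

| rule | decisive input | boundary | default |
|---|---|---|---|
| prefilter | DecisionMAF | `< 0.03` keeps the variant | `maf_threshold = 0.03` |
| BA1 | DecisionMAF | `> 0.05` | `ba1_threshold = 0.05` |
| PM2 (AD, AD/AR) | gnomAD allele count | `< 5` | fixed |
| PM2 (AR / XL) | homozygote / hemizygote count | `< 3` | fixed |
| BS2 | same counts | at/above the PM2 cutoff | disabled for late-onset genes |
| PM1 hotspot | pathogenic neighbors within window | `≥ 6` within `≤ 25` nt | fixed |
| PM1 domain | pathogenic / non-VUS ratio | `> 0.5`, ≥1 pathogenic | fixed |
| PP3/BP4 panel | concordant predictor calls | `≥ 3` | `concordance_mode = strict` |
| PP3/BP4 splice (intronic) | dbscSNV ADA, RF | `> 0.708`, `> 0.515` | fixed |

DecisionMAF is the maximum subpopulation frequency excluding the
Finnish, Ashkenazi, and "other" groups (bottlenecked/founder
populations inflate frequencies); the excluded set is a field of the
population record. All comparisons are strict exactly as tabulated
above; every boundary is covered by a monotone probe test on the live
engine, so the table documents behavior rather than stored constants.

Design choices where the specification of the source workflow was
genuinely open:

* **Concordance policy.** "At least three total and concordant
  predictors" is read strictly: ≥3 calls of one polarity and zero of
  the other. The upstream annotator observably assigns PP3 at 7-vs-5
  discordant calls; `concordance_mode = "majority"` (≥3 calls of the
  winning polarity holding >50% of the total) reproduces that behavior
  for comparison. Strict is the default because it matches the stated
  rule; the PIEZO1 c.5891T>C fixture yields VUS under either mode.
* **Inheritance override.** Curated gene–disease databases record one
  inheritance per gene, which can be wrong for the phenotype under
  test (PIEZO1: dominant stomatocytosis vs recessive lymphatic
  dysplasia). The effective model (AD / AR / XL / AD_AR) is therefore a
  per-run parameter layered over the gene context, not a property of
  the evidence.
* **X-linked branch.** XL-only genes use the hemizygote `< 3` cutoff
  (the recessive-like branch), and X-linked VUS fall in the Secondary
  report tier with the recessive genes.
* **Hotspot distance** is coding-sequence distance in nucleotides,
  inclusive at 25 (`≤ 25` counts). The upstream "proximity score"
  weighting has no published formula and is not implemented; the
  count-of-six rule alone triggers the branch, and the assignment
  rationale says so.
* **PM1 downgrade suggestion.** The criterion is flagged (not
  auto-downgraded) when the domain holds fewer than 10 classified
  variants or is larger than `pm1_domain_size_ceiling` (default 500
  aa; the motivating example is a 1056-aa domain called "very large"
  with no printed threshold). The decision to downgrade stays with the
  reviewer, matching the checklist.
* **BS1** has no universal frequency cutoff; it is auto-assigned only
  when a per-gene disorder-specific ceiling is configured, otherwise
  it is reviewer-only.
* **BP4 for intronic variants** mirrors the PP3 splice-score path
  (both scores present and at/below the cutoffs), since the checklist
  extends ADA/RF to the benign criterion for intronic variants.
* **Externally supplied criteria** merge into the automatic report
  tagged `external`; benign strengths are clamped on merge (BP6 is the
  criterion most often boosted upstream). If the engine explicitly
  withheld a code that arrives externally (e.g. PP3 with PVS1 active),
  the external call is kept with the disagreement noted in its
  rationale — removing it is a reviewer decision, which is exactly how
  the RIT1 case proceeds.

## Combination rules

Two independent implementations coexist: a procedural classifier
(`combine.classify`) and a declarative clause table (`table1`), a
literal transcription of the laboratory's modified combination table
with one predicate per printed clause. The test suite and the
`audit-rules` command enumerate all 5⁷ = 78,125 tallies with buckets
0..4 and require 100% agreement. Criteria count at *effective*
strength: PVS1 downgraded to Moderate increments the PM bucket, which
is what makes PVS1_Moderate + PM2 a VUS.

Suppression is deliberately narrow: exactly one BS-class criterion
together with ≥1 pathogenic criterion of any strength is ignored in the
verdict. With ≥2 BS criteria the benign clauses stand, and simultaneous
pathogenic and benign matches resolve to VUS as contradictory evidence.
BA1 is never suppressed; the hypomorphic exemption works upstream by
never assigning BA1 to allowlisted variants (ABCA4 c.5603A>T at ~7%
European frequency, TYR c.1205G>A at ~27%), which also carries them
through the benign report filter as phenotype modifiers.

## Reviewer checklist

Eleven criteria are manual-only (BS3, BS4, BP2, BP5, PS2, PS3, PS4,
PM3, PM6, PP1, PP4). The policy maps each criterion to its allowed
strengths: pathogenic criteria range over Supporting–VeryStrong unless
the checklist narrows them (PM1 ≤ Moderate; PS1 ∈ {Strong,
Supporting}; PM3/PP1 ≤ Strong; PP4 ≤ Moderate); benign criteria never
take Moderate/VeryStrong; BS1 may be used stand-alone only for
high-penetrance dominant disease, gated on the gene context. PM6 has
no automatic grade — the reviewer picks Supporting/Moderate/Strong with
a mandatory justification. Batches of adjustments are atomic: one
invalid action rejects the batch, leaving the automatic result intact.

The grading helpers are step functions with the checklist's printed
breakpoints: PP1 Supporting/Moderate/Strong at 1 / 2–3 / ≥4 affected
persons; PM3 Supporting for a single trans partner or homozygosity and
Strong for multiple partners or individuals; PP4 Moderate for
single-gene disorders and Supporting up to 5 associated genes; PS4
Strong with case–control data or ≥5 unrelated affected individuals.

## Synthetic evidence generator

`simulate.make_bundle` constructs, for a requested set of
auto-assignable criteria, a bundle whose decisive inputs sit one unit
(or 0.001 for real-valued scores) inside each targeted threshold and
whose remaining inputs sit outside every other threshold; `jitter`
randomizes the non-decisive fields from a seeded generator (same seed,
same bundle). Infeasible target sets — mutually exclusive pairs, or
codes pinned to conflicting transcript consequences — are rejected with
a reason. The generator emulates *annotation output*, not biology: it
produces no genotypes or reads, no linkage between frequency and
predictor values, and no realistic site-frequency spectrum. Passing
tests therefore demonstrate that the rule logic is correct at and
around every boundary, not that the thresholds are clinically optimal
on real cohorts — the source workflow's own validation is case-based,
and the case fixtures are reproduced exactly.

## Numerical and degenerate-input choices

Frequencies are compared as IEEE doubles with strict inequalities; no
tolerance is applied (inputs are table-derived decimals, not computed
quantities). A domain with zero classified non-VUS variants never
triggers the ratio branch (no division). Duplicate active criteria are
rejected by name. Missing inheritance produces exclusion records for
PM2/BS2 rather than an error. Report output is deterministic: fixed
column order, input row order, `repr`-formatted floats.

## Problem sizes

The test suite runs the exhaustive 78,125-state rule-table comparison,
hypothesis property suites at 60–300 examples each (derandomized), and
a 10,000-bundle invariant sweep; the verification script repeats the
enumeration, the boundary probes, the case-study fixtures, and the
10,000-bundle sweep. The whole suite completes in a few seconds on one
CPU.

## Known limitations

* PVS1 grading implements the NMD/last-exon and exon-edge rules plus
  acceptance of an externally computed strength; the full published
  LoF decision tree (exon-skipping domains, rescue transcripts) is out
  of scope.
* Verdicts are rule-combination only; no Bayesian/point-based scoring
  and no hot/cold VUS sub-tiers.
* The Primary/Secondary tier for X-linked genes follows the
  recessive-like branch; the source checklist does not state this case.
* The benign-filter exception list ("recommended" high-frequency
  pathogenic variants) ships empty apart from the two hypomorphic
  alleles; site-specific lists are config-supplied.
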