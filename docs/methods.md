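# Methods

`asc-time-kit` quantifies heterogeneity of the tumor immune
microenvironment between the two histological components of lung
adenosquamous carcinoma — the adenocarcinoma component (ACC) and the
squamous cell carcinoma component (SCCC) — and analyzes real-world
efficacy of immune-checkpoint-inhibitor (ICI) therapy in a bundled
46-patient cohort. This note documents the models, conventions and
numerical choices; it states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Immunophenotyping

Each component is scored at five random ×200 fields for the percent of
area occupied by mononuclear cells inside the tumor mass (intratumoral)
and in the stroma around the invasive border. Classification applies to
the arithmetic mean over fields, not a per-field vote:

* *inflamed* — mean intratumoral density ≥ 10%, regardless of stroma;
* *excluded* — intratumoral < 10%, stromal ≥ 10%;
* *desert* — both < 10%.

The 10% threshold (`til_cutoff`) is inclusive; the three predicates
partition [0, 100]² exactly, which the suite checks on a dense grid and
with property-based sampling. Component-level calls are primary. A
whole-sample roll-up is provided (`sample_phenotype`) because a single
per-patient label is sometimes wanted; the source data do not prescribe
one, so the default is the explicit *worst-case* rule — a sample is as
cold as its least-infiltrated component — and is flagged as an
interpretation layer, configurable to `best`.

## MIF quantification

Cell phenotypes are boolean gates over the eleven-marker panel (CD3,
CD4, CD8, CD57, CD68, CD163, FOXP3, PD1, PDL1, TIM3, LAG3): e.g.
regulatory T cells CD4⁺FOXP3⁺, NK cells CD57⁺ (deliberately without
negative requirements), M2 macrophages CD68⁺CD163⁺. Proportions are
reported per region (tumor, stroma) and for the *total* region, which
pools the cell counts of both regions — the sum of the areas — rather
than averaging the two percentages; the pooled total is therefore always
between the two region percentages. The denominator is all segmented
cells in the region. PD-L1 TPS is the percent of viable tumor cells with
membrane staining and requires ≥ 100 cells; staining partiality
(complete vs partial membrane) is collapsed into the single PDL1
boolean — intensity modeling is out of scope.

## Tumor mutation burden

Candidate somatic variants pass when VAF ≥ 2% (`vaf_min`), high-quality
supporting reads ≥ 5 (`min_hq_reads`; base Phred ≥ 30 and mapping
quality ≥ 30, pre-aggregated upstream) and no paired-end bias, all
inclusive. Rejects carry the first failing criterion in the fixed order
vaf → reads → bias, so reject reports are reproducible. TMB is the count
of *nonsynonymous* passing mutations divided by the 0.7-Mb targeted
coding region (`panel_mb`), i.e. reported per megabase. The whole-tumor
(union) TMB de-duplicates mutations across the paired components by
(chrom, pos, ref, alt) — trunk mutations count once; VAF is deliberately
excluded from the identity key.

## TCR repertoire

Diversity is the Shannon entropy H = −Σ pᵢ ln pᵢ over *productive
unique* CDR3 clonotypes, in nats; clonality is C = 1 − H / ln U with U
the productive unique count. The natural log is used on both sides so
that C ∈ [0, 1]. A singleton repertoire (U = 1) makes the formula 0/0
and is reported as C = 1 with a logged warning — a single expanded clone
is the limit of maximal dominance. Zero-count clones are rejected at the
type level rather than silently dropped.

## Paired statistics

Wilcoxon matched-pairs signed-rank (paired component comparisons),
Mann–Whitney U (unpaired) and Spearman rank correlation, with fixed
conventions: two-sided p by doubling the smaller tail, capped at 1;
signed-rank drops zero differences before ranking (Wilcoxon's original
convention, not Pratt's — `n_effective` reflects it) and is exact via
the dynamic-programming null distribution for n ≤ 25 without ties,
otherwise normally approximated with tie and continuity corrections;
the U test is exact for min(n) ≤ 8 without ties (Gaussian-binomial
recurrence); Spearman uses average ranks and full permutation
enumeration for n ≤ 9, otherwise the t approximation. The switchover
sizes are desk-scale enumeration limits, exposed as arguments. Exact
paths are validated against independent full-enumeration oracles (all
2ⁿ sign assignments; all C(n,k) rank subsets) and against SciPy. No
multiple-testing correction is applied by default; a Benjamini–Hochberg
helper exists but defaults off, matching the unadjusted reporting the
analyses assume.

## Survival and response

Best response is an adjudicated RECIST label; ORR = (CR+PR)/n and
DCR = (CR+PR+SD)/n are rounded half-up to integer percents (so 13/46
prints as 28%). Survival uses the Kaplan–Meier product-limit estimator
(fit via `lifelines`), events before censorings at tied times. The
median is the smallest *event* time with S(t) ≤ 0.5, inclusive; it is
undefined (∞, serialized as null) when the curve never reaches 0.5. The
95% CI of the median inverts the pointwise log(−log) Greenwood band
(Brookmeyer–Crowley); the source cohort does not state its CI method, so
CIs are reported but not treated as reference values. Subgroup
partitions (treatment, line, PD-L1 positivity at qualifier-aware
TPS ≥ 1%, driver status) place unknown-valued records in an explicit
`unknown` bucket. A reverse-KM median follow-up estimate is provided and
labeled as such. An independent brute-force product-limit oracle in the
test suite checks S(t) and the median on randomized instances (n ≤ 12)
and the no-censoring case against the empirical survival function.

## Bundled cohort

`data/table2.tsv` transcribes the 46-patient real-world cohort listing
verbatim, including internal oddities (a PR with 1.4-month PFS; a
censored PR at 1.7 months): transcription fidelity beats plausibility
correction. Status columns code 1 = event; "NA" cells become explicit
unknowns, never zeros. Censored TPS strings parse to a numeric value
plus qualifier ("<1%" → 0.5/lt, "≥50%" → 50/ge) so threshold subgrouping
honors the reported bound. Two subgroup medians printed in the source
(PD-L1-positive mono-ICI 6.8 and chemo-ICI 9.8 months PFS) recompute
*transposed* from the listed per-patient data under TPS ≥ 1%; the module
reports its recomputed values and takes no side on the discrepancy.

## Synthetic-data generators

Generators define the testing conditions; their defaults are the study
conditions, chosen once:

* **TIL fields** — per-phenotype mean boxes (inflamed intratumoral
  15–40%; excluded intratumoral 0–5% with stroma 15–40%; desert both
  0–5%) plus per-field Gaussian noise (default SD 2 points), clipped to
  [0, 100]. The boxes keep a 5-point margin to the 10% cut so 5-field
  means essentially always classify correctly (Monte-Carlo checked at
  ≥ 99%).
* **MIF cells** — a unit-disk tumor inside an annular stroma, region
  labels as ground truth (segmentation is out of scope). Per region each
  cell draws one phenotype multinomially from target percentages; the
  defaults encode the reported component medians (total region, %):
  PD-L1 8.5 vs 1.2, PD-1 4.7 vs 1.5, Treg 0.63 vs 0.58, NK 0.27 vs 0.71
  (SCCC vs ACC). All other markers flip positive independently at a
  0.2% false-positive rate to emulate staining noise. Note the Treg
  effect (0.05 percentage points) sits below binomial counting noise at
  the 4,000 cells/component used by the analysis driver, so that single
  comparison is expected to be underpowered at desk scale; the large
  checkpoint shifts are not.
* **Variants** — exact per-category counts (pass-nonsynonymous,
  pass-synonymous, and one violation each of the VAF, read and bias
  criteria), with `shared_k` calls copied identically into the partner
  component to emulate trunk mutations.
* **Repertoires** — a geometric clone-abundance series, chosen over a
  power law because its single decay parameter is monotone in clonality
  and invertible by bisection (tolerance 1e-6); frequencies are scaled
  to 100,000 integer templates and the emitted counts must land within
  0.01 of the target clonality, else the call errors naming the nearest
  achievable value.
* **Outcomes** — PFS and OS marginals exponential with the stated
  medians (rate = ln 2 / median). The two endpoints share one uniform
  draw (comonotone coupling): this keeps *both* marginal medians exact
  while guaranteeing OS ≥ PFS; an additive construction would distort
  the OS median. Censoring is an independent exponential follow-up time
  applied to both endpoints, its rate calibrated so the expected
  censored fraction of PFS equals `censor_rate`.

What the generators do not emulate: spatial clustering of immune cells,
between-field correlation beyond a shared mean, inter-sample biological
variance structure of real cohorts, sequencing depth effects on clone
detection, or non-exponential hazards. Passing parameter-recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to real-data pathologies.

## Problem sizes

The default suite and drivers use desk-scale sizes chosen to keep the
statistical tolerances honest: 10,000 null simulations for the type-I
error check (n = 20 pairs, exact mode), 2,000 synthetic patients for KM
median recovery (±3 standard errors), 50,000 cells for MIF proportion
recovery (±3 binomial SE), 28 simulated paired tumors in the analysis
drivers, and exhaustive enumeration oracles at n ≤ 8–12.

## Known limitations

Cohort-level numbers that require the deposited specimen sequencing
(component phenotype split, MIF/TMB/TCR medians, printed p-values) are
not reproduced — the pipeline is validated by construction (oracles,
closed forms, parameter recovery) instead. The tie/zero conventions of
the original statistics software are unknown, so printed p-values are
not reference-checked. RECIST labels arrive adjudicated; no
lesion-measurement computation. No Cox regression, log-rank tests or
landmark analyses are provided, as the analyses here use none.
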