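# Methods

## Model and procedure

The package implements a case-control collapsing burden analysis for
ultra-rare variants (URVs), followed by pathway and cell-type enrichment of
the resulting gene signals.

1. **URV selection.** Variants are annotated per transcript; annotations are
   reduced to one row per (variant, gene) by preferring the
   GENCODE-canonical transcript (ties: lexicographically smallest transcript
   id; no canonical flag at all: most severe consequence, order
   pLoF > inframe_indel > missense > synonymous > other, then smallest id).
   A variant is ultra-rare iff gnomAD control population-max allele
   frequency ≤ 1e-4 **and** cohort allele count ≤ 3, both inclusive.
   Missing population frequencies mean the variant is absent from gnomAD and
   are read as 0 (novel). The cohort allele count is computed over cases and
   controls jointly; carrier status is binary (heterozygous and homozygous
   carriers are equivalent), so the allele count equals the carrier count.
2. **Weighting and collapsing.** Weights live in [0, 1] and depend only on
   (consequence class, damaging-prediction tier). A gene-by-individual
   burden matrix holds the maximum carried weight. Genes with ≥ 10 distinct
   qualified (weight ≠ 0) variants enter testing.
3. **Association test.** The burden is dichotomized at thresholds
   {>0, ≥0.5, =1.0}; each threshold yields a 2×2 carrier table that is
   tested with a two-sided Fisher exact test; the per-threshold p-values are
   combined with the equal-weight Cauchy combination. Carrier counts and
   odds ratios are reported at burden > 0.
4. **Calibration and multiplicity.** Expected p-value order statistics are
   the mean over 1000 case/control label permutations of the sorted
   per-gene p-values (the case count is preserved by every shuffle). The
   genomic inflation factor is the median χ²(1)-transformed p divided by
   0.4549. q-values follow the Storey–Tibshirani step-down with a
   single-λ π₀ estimate.
5. **Enrichment.** Hit genes (combined p < 0.05) are tested against GMT
   gene sets with one-sided hypergeometric tests over the universe of tested
   (eligible) genes; fold = (k/n)/(K/N). Cell-type enrichment sums the hit
   genes' expression specificity per (cell type, stage) and compares it with
   1000 equally sized uniform random gene sets.

## Statistical choices for discrete component tests

Ultra-rare carrier tables are heavily discrete: a gene with ~45 carriers
among 4500 samples admits only a handful of attainable p-values, the modal
outcome has p = 1 exactly, and the conventional two-sided Fisher p is
sub-uniform under the null. Two consequences drove design decisions here:

- **p = 1 breaks the plain Cauchy combination.** tan((0.5 − p)π) → −∞ as
  p → 1, so a single component at 1 drags the combined p to 1 regardless of
  the other components. In a null cohort the median combined p was ≈ 0.9
  and λ_GC ≈ 0.07 under the naive formula. The public
  `cauchy_combine` therefore adopts the reference Cauchy-combination (CCT)
  handling: when any component equals 1 it returns the Bonferroni-style
  fallback min(1, d·min p).
- **Inside the gene test, mid-p components are combined.** The per-threshold
  components use the mid-p variant of the two-sided Fisher test (outcomes
  as likely as the observed one contribute half their probability). Mid-p
  values have null mean exactly 0.5 and are the standard discreteness
  correction when many discrete p-values are aggregated; without it the
  combined statistic is so conservative that empirical type-I error and
  λ_GC are far from nominal. Degenerate thresholds (a zero carrier margin,
  whose p is 1 under every relabeling) carry no information and are dropped
  from the combination; a gene with no informative threshold gets p = 1.
  The exposed `fisher_exact_2x2` keeps the conventional (non-mid)
  definition: the sum of same-margin table probabilities not exceeding the
  observed one.

Measured on null synthetic cohorts of the default shape (750 cases / 3750
controls, ≥ 2000 eligible genes), the resulting test has empirical type-I
error ≈ 0.045–0.050 at α = 0.05 for both weight tables, λ_GC ≈ 0.98 for the
single-component synonymous run and ≈ 0.87–0.89 for the three-threshold
functional run. The residual deflation of the functional λ is the known
center-conservatism of the Cauchy combination under strongly positively
dependent components (the three dichotomizations are nested); it does not
affect tail behavior, where the combination is accurate, and the
permutation-based expected quantiles track the observed ones closely.

## Parameters

| Parameter | Default | Meaning / rationale |
| --- | --- | --- |
| `popmax_max` | 1e-4 | URV population-frequency bound (0.01%) |
| `ac_max` | 3 | URV cohort allele-count bound |
| `min_qualified` | 10 | qualified variants needed for a gene to be tested |
| `thresholds` | (0, 0.5, 1.0) | burden dichotomization points; 0 means “> 0” |
| `n_perm` | 1000 | label permutations for expected p quantiles |
| `lambda_storey` | 0.5 | π₀ estimation point; estimate ≤ 0 falls back to π₀ = 1 (then q ≡ Benjamini–Hochberg) |
| `n_boot` | 1000 | bootstrap draws for cell-type enrichment |
| `hit_alpha` | 0.05 | nominal p cut defining the enrichment hit list |

Weight tables ship as `functional` (pLoF 1.0, in-frame indel 0.8, missense
0.8/0.5/0.2 by ≥2/1/0 damaging predictions, synonymous/other 0) and
`synonymous_calibration` (synonymous 1.0, all else 0 — a negative-control
run in which any association signal indicates miscalibration). Custom
tables load from YAML.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults emulate the statistical structure of a
sequencing study of ~750 undiagnosed cases against ~3740 controls:
thousands of genes, a Poisson number of variants per gene (mean 60),
consequence classes at fixed proportions (8% pLoF, 4% in-frame, 48%
missense, 28% synonymous, 12% other), and a population-frequency mixture
with half the variants novel (AF 0) and half log-uniform on [1e-7, 1e-2],
so the URV frequency filter has mass on both sides. Per-variant carrier
probability 3.2e-4 yields a gene-level qualified-carrier probability of
about 0.01.

Risk acts at the gene level: a case carries a qualifying variant in a risk
gene with probability p1 = R·p0/(1 − p0 + R·p0), the carrier odds-ratio
model. Gene-level carriers are distributed over the gene's qualifying
variants uniformly **subject to a per-variant allele-count cap of 3**:
ultra-rare variants are near-singletons by definition, and without the cap
the AC ≤ 3 filter would mechanically delete 30–40% of planted carriers and
the generator would no longer realize its own nominal p0 and odds ratio.
Variants that fail the frequency or weight criteria receive independent
background carriers at the per-variant rate.

The expression generator draws negative-binomial counts (mean 0.5,
dispersion 2) for 12 cell types across 5 developmental stages, multiplying
the mean of planted gene sets by a fold factor in one target cell type.

Not emulated: linkage disequilibrium, relatedness and population structure,
per-gene mutability differences, genotype dosage effects, sequencing depth
or batch artifacts, and cell-type abundance imbalance. Passing tests
therefore demonstrate the statistical machinery under exchangeable-label,
independence assumptions — not robustness to confounding, which in a real
study is handled upstream (ancestry matching, QC) or is out of scope.

## Numerical details

- Cauchy-combination inputs are clipped to [1e-16, 1 − 1e-16]; components
  ≥ 1 − 1e-9 are treated as exactly 1 (discrete tests produce p = 1 up to
  float summation error).
- Fisher tie comparison uses a 1 + 1e-7 relative slack on point
  probabilities (the same convention as the common implementations);
  against exact integer enumeration on all tables with margins ≤ 20 the
  implementation agrees to < 1e-12.
- Per-gene, per-threshold Fisher p-values are precomputed as lookup tables
  over all attainable case-carrier counts (margins are permutation
  invariant), which makes the 1000-fold permutation re-testing of ~2000
  genes take seconds.
- Odds ratios apply the Haldane–Anscombe +0.5 correction only when a cell
  is zero.
- Zero bootstrap variance in cell-type enrichment reports p = 1 with z
  undefined (NaN) rather than ±∞; bootstrap p carries an add-one
  correction, so p ∈ [1/(n_boot+1), 1].
- Cell-depth normalization scales each cell to the stage's median total
  count; genes unexpressed within a stage are excluded from that stage's
  specificity matrix and from bootstrap backgrounds.
- Cohort-summary percentages round half-up to one decimal, matching
  clinical-table convention.

## Open design points, resolved

- *How the weighted burden enters the test*: dichotomization at a threshold
  set, Fisher per threshold, Cauchy combination — uses only the max-weight
  burden, a two-sided exact test and the Cauchy combination. Per-variant
  combination (ACAT-V-style) was not adopted because single-URV tables are
  even more discrete.
- *Enrichment universe*: all genes that entered the burden test, since hits
  are defined among tested genes.
- *Specificity per stage*: computed independently per stage because
  enrichment is reported per (cell type, stage) and stages are separate
  samples.
- *Bootstrap backgrounds*: uniform without-replacement draws; no GC/length
  matching.

## Known limitations

- λ_GC of the three-threshold functional combination sits around 0.87–0.89
  on null cohorts (center-conservative; see above). Single-threshold runs
  are calibrated at ≈ 0.99.
- With five genes planted at OR = 4 over a 400-gene panel, the median
  estimated odds ratio is ≈ 4.0 and ≥4/5 genes reach q < 0.05 in roughly
  90% of seeds (batch estimates 0.88–0.92; 0.915 ± 0.020 over 200 cohorts)
  — the detection rate hovers at that boundary because ~28 expected case
  carriers leave substantial binomial noise per gene.
- Test-suite and acceptance problem sizes (2100–2700 genes for calibration,
  100 × 400-gene cohorts for recovery, 2000 genes × 5000 cells for
  enrichment) are the package's chosen desk-scale conditions; all scale
  linearly if larger runs are wanted.
- The pipeline offers no covariate adjustment (ancestry, sex) and no
  variance-component (SKAT-type) test; these are deliberate non-goals.
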