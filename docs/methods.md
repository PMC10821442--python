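# Methods

## The analysis model

The pipeline asks two questions of a newborn-screening (NBS) cohort: do
blood marker levels differ systematically with maternal age (MA) at
delivery, and do those differences propagate into screening false positives?

Marker-level differences are measured as standardized mean differences
(Cohen's d with the pooled standard deviation, sample variances on n−1
denominators) between each 5-year MA group and the 15–19-year baseline
group.  Effect sizes rather than p-values are used because at cohort scale
(hundreds of thousands of infants) even trivial mean differences are
"significant"; the |d| > 0.2 threshold is the conventional boundary of a
small-but-real effect.  No Hedges small-sample correction is applied — the
correction factor is 1 − 3/(4n−9), which is below 10⁻⁵ at the group sizes
involved; the implementation reports group moments so a corrected value can
be derived if wanted.  Flagging uses the absolute value of d: a marker
counts as MA-related if any comparison group exceeds the threshold (the
"at least one group" reading; the stricter all-groups rule can be obtained
from the stored matrix).  The advanced-MA analysis pools the 35–39 and
40–44 bands into one comparison sample and is run on the cohort restricted
to normal-birth-weight term infants, which removes most of the
prematurity-related confounding at the cost of sample size.

False-positive (FP) enrichment is an observed-vs-expected comparison: if
being a false positive were independent of maternal age, the share of FP
cases in the advanced group would equal the screen-negative share
p_advanced, so expected = n_fp × p_advanced.  The test is a Pearson 2×2
chi-squared (FP / screen-negative × advanced / not advanced) without
continuity correction; with a screen-negative margin of ~400k the
correction is immaterial, and it is available as an option for small
tables.  Expected counts are reported both as the raw float and rounded
half-away-from-zero.  The AaBC sensitivity variant drops FP cases sampled
before 24 h; by default the screen-negative denominator is recomputed under
the same restriction (symmetry), with an option to leave it unrestricted
since either convention is defensible.

## Statistical conventions

- **t-test**: Welch (unequal variances).  At cohort scale Welch and pooled
  t are indistinguishable; Welch is the safer default.
- **"Proportion tests"**: Pearson chi-squared homogeneity tests on the
  group × outcome count table, no continuity correction (k > 2 groups).
- **Clustering**: agglomerative, Euclidean distance on the marker rows of
  the d-matrix, average linkage (the convention of heatmap packages;
  single/complete/ward are selectable).  The tree is cut at k = 2; the
  cluster with the higher mean d is labelled *increasing*.  Dendrogram leaf
  order is inherently ambiguous (each merge can flip), so it is made
  deterministic by orienting the higher-mean-d subtree first at every
  merge; the increasing cluster therefore leads, and leaves are ordered by
  decreasing mean d within the tree's constraints.
- **Acylcarnitine enrichment**: a two-sample one-sided Kolmogorov–Smirnov
  test comparing leaf-rank positions of acylcarnitine vs non-acylcarnitine
  markers, alternative "acylcarnitines toward the top".  A rank-permutation
  Monte-Carlo p-value is available as a cross-check
  (`method="permutation"`); the two agree closely away from the extreme
  tail.  The construction (two-sample on leaf ranks) was chosen over a
  one-sample rank-uniformity test because it conditions on the observed
  class sizes and needs no continuity assumption.
- **Trend curves**: ordinary least squares on a cubic B-spline basis in MA
  (default 6 degrees of freedom, capped when a stratum spans few distinct
  ages), evaluated on the integer MA grid with the pointwise 95% confidence
  band of the mean.  The smoother is a visualization device; the contract
  it must satisfy — covering a linear truth at ≥ 90% of grid points and
  tracking monotone signals — is what the tests pin down, not a particular
  basis or penalty.  Regression splines satisfy this and keep the estimator
  linear and fast at ~500k rows.

## The synthetic-cohort generator

Real population NBS data are access-restricted, so the generator emulates
the structure the analysis relies on.  One record is one infant with
maternal age (integer years, drawn from a discretized normal with mean
29.5 y and SD 6 y over ages 12–50 — deliberately wider than the 15–44
analysis range so the MA filter has work to do), gestational age, birth
weight (normal around a GA-dependent mean), AaBC (lognormal, median 36 h),
sex (51.9% male), parent-reported ethnicity (17 detailed categories;
17.9% with multiple categories, 2.0% unknown), TPN and transfusion status,
and 46 marker levels.

Marker levels are drawn per marker from either a lognormal family (default
for generic scenarios: NBS analytes are right-skewed; levels are positive
by construction) or a normal family truncated at zero.  Planted effects are
standardized shifts added on the scale on which effect sizes are computed:
raw levels for the normal family, log levels for the lognormal family
(approximately equal to the raw-level d for small shifts).  The
*paper-analogue* default scenario (`paper_analogue_config`) uses the normal
family with unit scale and a location far from zero, so a planted shift of
0.29 is recovered as Cohen's d = 0.29 up to sampling noise — this is the
calibration-grade configuration used for effect-size recovery checks.

Planted structure in the default scenario:

- **Signature markers**: rise-then-plateau curves reaching 0.29 (C16),
  0.22 (C3DC), 0.30 (C14), 0.27 (C18), 0.32 (C18:1) in the 35–39 and 40–44
  groups; a monotone decrease to −0.43 for C5OH; a non-monotone hump for C3
  (peak 0.25 in mid groups, back to ~0.14 pooled advanced, so C3 is flagged
  in the six-group analysis but not advanced-vs-baseline); a shallow U for
  C0 and a small drift for ARG, both below threshold.
- **Class-wide drifts**: the remaining acylcarnitines get small positive
  rise-then-plateau curves (amplitudes 0.04–0.12) and the amino acids small
  negative ones (−0.03 to −0.10), all far below the 0.2 threshold relative
  to the sampling noise at cohort scale.  This reproduces the global
  heatmap structure — an increasing cluster enriched in acylcarnitines at
  the top, a decreasing cluster at the bottom — and gives the enrichment
  test its signal.
- **Covariate influences** on the three disease markers: male +0.08–0.10,
  preterm −0.08–−0.12, major-ethnicity shifts up to 0.12, AaBC-band shifts
  up to 0.08 (term and male infants highest for all three).  Magnitudes are
  kept ≤ 0.12 SD and ethnicity MA offsets modest so that
  confounding-induced bias on the planted d values stays well below the
  ±0.025 recovery tolerance (the residual attenuation from
  covariate-mixture variance is ≲ 0.005).
- **MA–covariate structure**: per-ethnicity MA offsets (Korean and Japanese
  calibrated to unfiltered means of 33.9 y and 35.1 y, Asian/White above
  Hispanic/Black), applied with stochastic rounding to keep ages integral
  without biasing the mean; U-shaped preterm probabilities per MA group
  with the minimum at 20–24 y for Black/Hispanic and 25–29 y for
  Asian/White infants.
- **Screening labels**: a record is labelled a false positive for a
  disorder exactly when its disease-marker level strictly exceeds a cutoff
  (ties negative; multiple exceedances resolve in the fixed order MAL,
  CPT-II, 3MCC).  The pipeline sets cutoffs at marker-level quantiles tuned
  to population FP rates of roughly 0.87‰ (MAL), 0.10‰ (CPT-II) and 0.47‰
  (3MCC).  FP enrichment at advanced MA is therefore an *emergent* property
  of the planted marker shifts, not planted directly.
- A small configured fraction of records carries unknown AaBC/TPN/
  transfusion/ethnicity and out-of-range GA/BW/MA so that every exclusion
  rule is exercised.

What the generator does **not** emulate: assay measurement error and batch
structure, kit-lot and seasonal effects, multiple-birth status, correlation
between markers beyond shared covariate effects, true-positive (affected)
infants, and the skew/kurtosis details of real analyte distributions in the
calibration family.  Passing tests therefore demonstrate that the analysis
machinery recovers known planted structure at realistic scale — not that
the real Californian effect sizes are what the scenario plants.

## The exclusion filters

Rule text of the form "less than 1000 g or larger than 5000 g" is read
strictly, so boundary values (BW exactly 1000/5000 g, GA 28/42 w, AaBC
12/168 h, MA 15/44 y) are retained; the boundary tests pin this choice.
Removals are attributed to the first failing rule in the order R1 (BW),
R2 (GA), R3 (AaBC), R4 (TPN), R5 (transfusion), R6 (MA) — attribution is
diagnostic only; the retained set is order-independent and the report
counts reconcile exactly with the input.  Preterm is GA ≤ 36 weeks.  For
false-positive case records the transfusion rule is skipped, since
transfusion status is unavailable for them.  Singleton status is assumed
upstream and is not a field.  The 17→4 major-ethnicity mapping groups the
nine Asian-origin categories as Asian and Middle Eastern with White, and
leaves Guamanian, Hawaiian, Samoan and Native American outside the four
major groups; the mapping is a package default (exposed as
`MAJOR_GROUP_MAP`) — other conventions are defensible and the mapping is
configurable in analyses that take a grouping argument.

## Numerical and degenerate-input choices

- Cohen's d with zero pooled SD raises an explicit undefined-effect error,
  never a silent 0; groups with fewer than 2 records yield NaN cells in the
  profile matrix (an empty baseline is an error).
- Determinism: every stochastic step flows from one `numpy` Generator
  seeded by the config; identical seed and configuration give byte-identical
  cohort tables and identical reports (timings live only in the run
  manifest).  The pipeline configuration hash is computed over
  canonically-sorted JSON, so it is stable under key reordering.
- Unknown values are NaN (numeric) or `unknown`/empty (categorical) in
  memory and `NA`/`U` in files; one documented dialect, round-trip tested.
- Chi-squared tests attach a warning flag when an expected cell is below 5
  but still compute.

## Problem sizes

The shipped default scenario is 500,000 infants (the scale at which the
flag threshold has a comfortable noise margin: the d standard error is
~0.008 at the resulting group sizes, so the 0.22-vs-0.20 margin is ~2.4
SE).  The acceptance script uses exact group sizes of 17,063 baseline and
90,191 advanced (averaging d over 10 seeds, taking the modal flag count)
and 20,000 records per MA group for the six-group profile (modal count over
5 seeds); it completes in well under a minute.  Unit and property tests use
1k–150k-record cohorts, 20–50-seed Monte-Carlo loops and 1,000-replicate
null calibrations.

## Known limitations

- The generator's effect curves are step functions over 5-year MA groups;
  smooth age trends within groups are not modelled (trend-curve behaviour
  is tested on separately constructed smooth-signal data).
- The false-positive mechanism is a single fixed cutoff per disorder; real
  screening uses age- and weight-adjusted cutoffs and second-tier tests, so
  synthetic FP rates and excesses are qualitative analogues only.
- Multiple-ethnicity records are generated as two independent draws, not as
  a realistic admixture model; they are removed by the ethnicity filter in
  any case.
- Effect sizes are computed on raw levels by default (a log-level switch is
  provided); whether a real deployment should standardize to
  multiples-of-median first is a data-dependent choice the package does not
  make.
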