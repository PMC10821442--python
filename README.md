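# nbsma — maternal-age effects on newborn-screening metabolite panels

Population newborn screening (NBS) measures dozens of blood metabolites in
dried blood spots to detect treatable inborn metabolic disorders.  Metabolite
levels are known to vary with gestational age, birth weight, age at blood
collection (AaBC), infant sex and parent-reported ethnicity — and also with
maternal age (MA) at delivery.  `nbsma` is a reusable, fully tested pipeline
for quantifying maternal-age-related differences in NBS marker levels and
their downstream effect on screening false positives, aimed at biostatistics
and NBS-program analysts.  Because population NBS data are access-restricted,
the package ships a seeded synthetic-cohort generator that emulates the
relevant statistical structure, so every stage is runnable and testable end
to end.

## What it computes

Given a cohort table (one row per infant: covariates plus 46 marker levels),
the pipeline runs:

1. **Exclusion filters** — remove infants with birth weight outside
   1000–5000 g, gestational age outside 28–42 weeks, AaBC unknown or outside
   12–168 h, TPN or transfusion positive/unknown, MA outside 15–44 years;
   plus an ethnicity filter (single reported category only) and a stricter
   normal-birth-weight term restriction (2500–4000 g, 37–42 weeks) for the
   false-positive analysis.
2. **Effect-size profiles** — for each marker *m* and each 5-year MA group
   *g* (baseline: 15–19 years), Cohen's d with the pooled SD:

   d = (x̄_g − x̄_base) / s_p,  s_p² = ((n_g−1)s_g² + (n_b−1)s_b²) / (n_g+n_b−2)

   Markers with max_g |d| > 0.2 are flagged.  A second comparison pools MA
   ≥ 35 ("advanced") against the baseline.
3. **Clustering and enrichment** — hierarchical clustering (Euclidean,
   average linkage) of the marker × group d-matrix, a 2-cut into
   increasing/decreasing clusters, and a one-sided two-sample
   Kolmogorov–Smirnov test for acylcarnitines ranking toward the top.
4. **Covariate tests** — Welch t-test of MA by infant sex, one-way ANOVA of
   MA across ethnicity groups, chi-squared homogeneity of the preterm
   proportion across MA groups, and spline-smoothed marker-vs-MA trend
   curves with 95% bands, stratified by sex / term status / ethnicity.
5. **False-positive enrichment** — for disorders screened by elevated
   markers (malonic acidemia via C3DC, CPT-II deficiency via C16, 3MCC
   deficiency via C5OH), compares observed false-positive counts in the
   advanced-MA group against `n_fp × p_advanced` expected, with a 2×2
   chi-squared test and an AaBC ≥ 24 h sensitivity variant.

## Worked example

```python
import nbsma

report, manifest = nbsma.run_pipeline(seed=1)   # default 500k-infant scenario

print(report["effects"]["flagged"])
# ['C14', 'C16', 'C18', 'C18:1', 'C3', 'C3DC', 'C5OH']
print(report["fpanalysis"]["advanced_effects"]["flagged"])
# ['C14', 'C16', 'C18', 'C18:1', 'C3DC', 'C5OH']
```

Seven markers exceed |d| > 0.2 in at least one MA-group comparison; six of
them (13% of the 46-marker panel) persist when the advanced group (MA ≥ 35)
is compared with the baseline directly — the advanced-group effect sizes for
the three disease markers come out at d ≈ 0.22 (C3DC), 0.30 (C16) and −0.43
(C5OH), matching the shifts the default scenario plants.  Acylcarnitines are
enriched at the top of the clustering (KS p ≈ 2×10⁻⁹ in this run), and the
elevated C3DC translates into a false-positive excess for malonic acidemia
in the advanced-MA group (89 observed vs 67 expected, p = 0.0029), while the
decreased C5OH produces the opposite pattern for 3MCC.

The same stages are available from a shell:

```bash
nbsma run --seed 1 --out-dir out/          # report.json, manifest.json, figures
nbsma simulate --seed 1 --n 50000 --out cohort.tsv
nbsma filter --in cohort.tsv --mode core --out filtered.tsv --report filter.json
nbsma effects --in filtered.tsv --mode advanced --out effects.tsv
```

Figures produced by `nbsma run` (or `nbsma report`): the clustered
effect-size heatmap, per-covariate trend curves for C16/C3DC/C5OH, and the
ranked advanced-vs-baseline effect-size chart.

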