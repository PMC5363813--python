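# stemdist

Tumor differentiation scoring by expression distance from stem cells.

Histologic grading ties a tumor's prognosis to how poorly differentiated it
looks. `stemdist` makes that idea quantitative for transcriptomic cohorts:
every sample's log2 expression profile is compared against a stem-cell
reference centroid (hESC-, hMSC- or CD34+-style replicate averages), and the
resulting distance — samples closest to stem cells are the least
differentiated and highest risk — is used as a univariate predictor of
survival. The package is aimed at computational biologists who have a
genes × samples expression matrix, matching survival data, and a handful of
stem-cell reference profiles on the same platform.

## The model

For gene *i* with values *g<sub>i</sub>* across samples, the gene filter is

```
F(g_i) = 0                  if max(g_i) < log2(100)
       = 1                  else if IQR(g_i) >= c * median(IQR(g))
       = 0                  otherwise
```

so low-expressed genes are removed first and the remainder is thresholded on
interquartile range relative to the median IQR (c = 1 drops the less variable
half; the equivalent retained-fraction form drives the tuning grid of
top 5%, 10%, …, 95%). Over the retained genes, each sample's distance from
the reference centroid is either the Pearson correlation distance `1 − r` or
the Euclidean distance. The distance enters a univariate Cox
proportional-hazards model, whose quality is summarized by the Gönen–Heller
concordance probability estimate (CPE): each unordered sample pair
contributes `1/(1 + exp(−|η_i − η_j|))` with `η = β̂ · score`, so 0.5 is a
random model and 1.0 a perfect one. Tuning grids over
(reference, metric, retained fraction) score each combination by 5-fold
cross-validated CPE repeated with random folds; without survival data the
recommended defaults are the Pearson distance with a c = 2 filter.

Downstream, the package derives parsimonious gene signatures (per-cohort
regression of distance on standardized expression, pooled across cohorts by
inverse-variance fixed-effects meta-analysis, top genes by |z|), stratifies
patients into tertile risk groups compared by log-rank test, and builds
neighbor-joining dendrograms in which the stem-cell centroids sit as anchor
leaves. A synthetic-cohort generator with a planted differentiation axis and
exponential proportional-hazards survival makes the whole pipeline testable
without external data.

## Worked example

```sh
stemdist simulate --n-samples 80 --n-genes 200 --seed 5 --out sim/
stemdist distance --expr sim/expression.tsv --ref sim/reference.tsv \
    --ref-label hESC --retain-fraction 0.25 --out dist/
stemdist fit --scores dist/distances.tsv --clinical sim/clinical.tsv --out fit/
cat fit/cox_fit.json
```

```json
{
  "coefficient": -4.796805146602452,
  "se": 2.156334652455951,
  "hazard_ratio": 0.008256081929982308,
  "ci_low": 0.00012058647783664582,
  "ci_high": 0.5652614626236802,
  "p_value": 0.026113615995493,
  "n": 80,
  "n_events": 62
}
```

The negative coefficient is the expected orientation: *smaller* distance from
the stem-cell centroid means higher hazard, so risk decreases as samples move
away from the reference (hazard ratio per unit distance well below 1,
p ≈ 0.026 on this small simulated cohort). `stemdist stratify` then trisects
normalized scores into low/medium/high groups, `stemdist tune` sweeps the
full 19-fraction × 2-metric grid per reference, and `stemdist tree` writes a
Newick dendrogram with the hESC centroid as an anchor leaf.

The same steps are available as library calls (`simulate_cohort`,
`stem_cell_distances`, `fit_cox_univariate`, `grid_search`,
`build_signature`, `build_nj_tree`, …); see `docs/methods.md` for the
modelling details and parameter choices.

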