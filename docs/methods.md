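# Methods

## The stem-cell distance model

The package treats tumor differentiation as a position along an axis anchored
by stem-cell expression. Three tunable choices define the distance of a
sample from a stem-cell reference:

1. **Gene filter.** A gene is used only if its maximum log2 expression
   reaches `log2(100)` (≈ 6.64; genes below are treated as background) *and*
   its interquartile range across the patient samples is at least
   `c × median(IQR)` over all genes. The median is taken over **all** genes,
   including floor-failing ones — the literal reading of the filter formula;
   the alternative (median over floor-passing genes only) changes little on
   realistic matrices but is not used. The retained-fraction form
   (`filter_by_retained_fraction`) keeps the `ceil(fraction × n_genes)`
   highest-IQR genes among floor-passers; this is what the tuning grid of
   5%, 10%, …, 95% (19 levels) sweeps. All quantiles use linear
   interpolation, everywhere in the package. IQR ties at the cutoff are kept
   (`≥` comparison); in the top-k form ties break lexicographically by gene
   id so masks are deterministic.
2. **Metric.** Pearson correlation distance `1 − r` (unitless, in [0, 2]) or
   Euclidean distance (log2 units). The Pearson distance is invariant to
   positive affine transforms of either profile, which makes it the robust
   default across platforms.
3. **Reference.** A per-gene arithmetic mean of a few stem-cell replicates
   (e.g. hESC triplicates, CD34+ decades). The filter mask is computed from
   the patient cohort's IQRs only — the references never enter the IQR pool,
   since the filter's job is to denoise the patient-side signal — and is then
   intersected with the reference's genes (missing genes dropped with a
   warning). No cross-batch renormalization is attempted; cohort and
   reference are assumed to share a platform and scale, which is a real
   limitation on heterogeneous data.

All internal computation assumes log2 scale. Linear input must be declared
(`transform="log2"` applies `log2(x+1)`); missing values are rejected rather
than imputed.

## Survival evaluation

The distance enters a univariate Cox proportional-hazards model. The partial
likelihood is maximized by a damped Newton iteration written for the
univariate case (Efron approximation for tied event times; Wald standard
errors from the observed information). A dedicated solver is used because
tuning evaluates on the order of 10⁵ univariate fits; the implementation is
cross-checked against lifelines' `CoxPHFitter` in the test suite, with and
without ties, to ~1e-4 in coefficient and SE.

Model quality is the Gönen–Heller concordance probability estimate (CPE):
with linear predictor `η_i = β̂·score_i`, each unordered pair contributes
`1/(1+exp(−|η_i − η_j|))` and the CPE is the pair mean. Properties that
matter here:

- it is model-based — censoring times never enter — so a train-fitted `β̂`
  can be evaluated on a held-out fold's scores alone;
- `β̂ = 0` gives exactly 0.5 (the random-model convention), and tied linear
  predictors contribute 0.5 each;
- it is bounded below by 0.5 by construction, so even null fits sit slightly
  above 0.5 (≈ 0.51 at n = 500) because `|β̂| > 0` almost surely. The null
  calibration check asserts the mean over seeds stays within 0.02 of 0.5.

A brute-force Harrell's C over censoring-comparable pairs (shorter time must
be an event; score ties count 0.5; tied-time pairs are excluded) is the
independent empirical oracle; on large uncensored proportional-hazards
simulations the two agree within 0.02.

Risk scores from different predictors are made comparable by centering to
mean 0 and scaling to IQR 1 — the operational reading of the stated
postcondition. Tertile stratification cuts at the 1/3 and 2/3 quantiles
(samples exactly at a threshold go to the lower group; with n not divisible
by 3 the larger group is the low one), or at externally supplied
training-derived cutpoints. Group comparison is the k-group log-rank test
(delegated to lifelines).

## Tuning

For each (reference, metric, retained fraction) combination the distances
are computed **once** on the full cohort — the distance uses no outcome
labels, so this is not leakage — and only the Cox fit is cross-validated:
5 random folds, fit on 4, CPE of the train coefficient on the held-out
fold's scores; fold CPEs are averaged per repeat (unweighted) and then over
repeats (default 100). A strict variant that re-derives the IQR mask inside
each training fold is available (`mask_per_fold=True`) for users who want
the mask treated as supervised. Folds whose training part has fewer than two
events are skipped with a warning.

Seeding: each combination's RNG seed derives from
`SeedSequence([master_seed, reference_index, metric_code, round(fraction·10⁴)])`,
so results are bitwise reproducible and adding grid points never changes
existing rows. Ties in mean CPE break toward the larger fraction, then
Pearson before Euclidean, then reference input order.

Without survival data for tuning, the package's no-training default is the
Pearson distance with a `c = 2` filter (genes with IQR above twice the
median IQR).

## Signatures

Within each cohort, genes with zero variance are removed, every remaining
gene is standardized (mean 0, SD 1, ddof = 1), and the distance is regressed
on it by least squares (slope in distance units per expression SD; residual
SE with n − 2 df). Standardization inside each cohort is what makes slopes
poolable across platforms — pooling raw slopes from heterogeneous arrays
would mix units. Cohort slopes are pooled per gene by inverse-variance
fixed-effects meta-analysis (`w = 1/se²`), the standard scheme and the
default of the usual meta-analysis tooling; genes must appear in every
cohort to be pooled (strict mode), mirroring the zero-variance removal rule.
Genes are ranked by |z| = |pooled β / pooled SE| (an inference-style reading
of "most associated"; ranking by |β| is exposed as an option). The top 500
form the enrichment-scale signature; scoring uses the top 200: a sample's
score is `Σ β_g · z_g(sample)` over signature genes standardized within the
scored cohort. The score tracks the *distance*, so high score = far from
stem cells = low risk; the orientation must be flipped when reporting it as
mortality risk.

## Dendrograms

Patient samples plus the reference centroids form one pairwise distance
matrix on the same mask/metric as the survival analysis (the default; the
full-gene alternative is one flag away). Agglomeration is classic neighbor
joining (Studier–Keppler Q criterion), chosen over balanced minimum
evolution because it is deterministic, consistent on additive inputs, and
the downstream use — visual ordering of a cohort against stem-cell anchors —
does not hinge on BME refinements. Determinism: Q ties break on the
lexicographically smallest label pair, internal nodes carrying the smallest
leaf label beneath them. Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling edge. Trees are unrooted; Newick
export (via dendropy) quotes labels that need it, and the test suite checks
path-length-matrix round trips at 1e-9 and exact recovery on additive 4- and
5-leaf matrices, cross-checked against an independent NJ implementation.

## Synthetic cohorts

The generator plants exactly the structure the method presumes: stemness
`t_j ~ Uniform(0,1)`, stem centroid `s_g ~ Normal(8, 2²)` log2 units, a
flagged gene fraction with differentiated offsets `δ_g ~ Normal(0, delta_sd²)`,
expression `x = t·s + (1−t)·(s+δ) + Normal(0, noise_sd²)`, reference
replicates `s + noise`, and survival `Exponential(rate = baseline·exp(β_true·t))`
with independent exponential censoring. Defaults: n = 300 samples,
2000 genes, 20% informative genes, `delta_sd = 2`, `noise_sd = 1`,
`β_true = 1.5`, baseline hazard 0.02/month, censoring 0.01/month (≈ 80%
observed events), 3 reference replicates.

Two deliberate design points:

- **Information ceiling.** With uniform stemness and `β_true = 1.5`, the
  model-based concordance of even the *true* risk variable is
  `∫ 2(1−d)·expit(1.5d) dd ≈ 0.619`. Cross-validated CPEs on the planted
  cohort should therefore be judged against this ceiling, not against
  absolute levels like 0.65+, which this generative model cannot produce at
  the default effect size. The tuning test asserts near-ceiling recovery
  (within 0.02).
- **Fixed-magnitude offsets for recovery benchmarks.** Under Gaussian
  offsets, ~12% of "planted" genes land at |δ| < 0.3 — statistically
  indistinguishable from null at any realistic cohort size — so top-k
  recovery of planted genes is ill-posed. `fixed_effect_magnitude=True`
  plants offsets of magnitude `delta_sd` with random sign; the planted-gene
  recovery benchmark (50 planted among 2000, 4 cohorts) uses it so that
  "recovered" is well defined for every planted gene. The default remains
  the Gaussian model.

What the generator does *not* emulate: probe-level noise structure, batch
effects, platform differences between cohort and reference, non-proportional
hazards, or informative censoring. Passing tests therefore demonstrate
correctness of the machinery under the model's own premise, not robustness
of the biological claim on real arrays.

## Numerical conventions and edge cases

- Quantiles: linear interpolation throughout (filter, normalization,
  tertiles).
- Cox solver: covariate centered before iteration; step halving on partial-
  likelihood decrease; convergence at |step| < 1e-10·(1+|β|); non-positive
  information raises (constant scores are rejected upfront).
- Pearson distance on a constant profile raises (correlation undefined);
  distances are clipped into [0, 2] against float drift.
- `per_gene_association` requires ≥ 4 samples; pooling rejects non-positive
  SEs.
- Problem sizes in the test and acceptance runs (cohorts of 60–1500 samples,
  200–2000 genes, 1–100 CV repeats, 20-seed replications) were chosen as the
  smallest scales at which the Monte-Carlo tolerances above are comfortably
  resolved.

## Known limitations

- Intersection semantics assume a shared gene universe; no ortholog or probe
  mapping is attempted.
- The CPE's ≥ 0.5 floor means "no signal" manifests as slightly-above-0.5,
  not 0.5 exactly; comparisons between models should use differences, not
  absolute levels.
- Neighbor joining replaces balanced-minimum-evolution tree search; on
  strongly non-additive matrices the two can differ in topology.
- The multivariable clinical-covariate extension (ridged regression) is out
  of scope; only the univariate risk variable is modelled.
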