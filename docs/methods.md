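# Methods

## Problem and model

`prrtkit` re-implements, as a reusable and fully tested pipeline, a two-level
machine-learning analysis of somatostatin-receptor (SSTR) imaging in
metastatic neuroendocrine neoplasms (NEN). The clinical question is whether
peptide receptor radionuclide therapy (PRRT) eligibility — normally read off
SSTR SPECT/CT as a Krenning grade — can be predicted from clinical,
pathological, immunohistochemical and laboratory variables, and which
variables drive the prediction.

The analysis runs at two levels:

* **lesion level** — one row per imaged lesion; the outcome is the lesion's
  Krenning grade (binned 0–1 / 2 / 3–4) or its binary PRRT flag
  (grade ≥ 3);
* **patient level** — one row per patient; a patient is PRRT-eligible only
  if their *least active* lesion still reaches grade 3, i.e. eligibility is
  the conjunction of the per-lesion flags.

### Krenning scoring

Lesion uptake is expressed as unitless ratios against two reference organs.
With `tol = 0.1` and `background_cut = 0.2` (both configurable):

| grade | rule |
|---|---|
| 4 | `ratio_spleen > 1` |
| 3 | `ratio_liver > 1 + tol` |
| 2 | `ratio_liver ∈ [1 − tol, 1 + tol]` |
| 1 | `ratio_liver > background_cut` |
| 0 | otherwise |

The clinical scale is qualitative; the `tol` band ("comparable to liver")
and the grade-1 floor are this package's declared numeric conventions, chosen
so the mapping is deterministic and monotone non-decreasing in each ratio.
The upper edge of the grade-2 band is closed (a ratio of exactly `1 + tol`
scores 2); lower band edges resolve upward.

## The bench

For every configuration — learner × {SMOTE, none} × variable-group subset ×
target — the data are split into 80% training / 20% test `n_splits` times
(simple random row splits by default; a patient-grouped option keeps all of
one patient's lesions on the same side and is used where within-patient
memorisation would contaminate a comparison). Per split:

1. imputation/encoding is fit on training rows only: numeric columns take
   the training median, binary columns the training mode plus a
   missing-indicator column when the training column has gaps; all-missing
   training columns are dropped with a warning;
2. optionally, SMOTE balances the training classes: each synthetic minority
   point is `x + λ(x_nn − x)` with `λ ~ U[0, 1)` and `x_nn` among the k = 5
   nearest minority neighbours (Euclidean); test rows are never touched;
3. the model is fit and scored by F1 on the untouched test rows — binary F1
   (positive class = PRRT-suitable) for the two-class targets, macro F1 for
   the 3-bin Krenning target.

Learners: `linear` (L2 logistic regression on standardised features; run as
a baseline, excluded from feature importance), `bagged_trees` (random
forest), `boosted_trees` (gradient boosting / XGBoost). Hyperparameters are
fixed, not tuned: 500 trees at full scale (100 at desk scale), boosting depth
3, learning rate 0.1. Per-split seeds are `seed + split_index`. Failed cells
(e.g. a single-class training draw) are recorded and excluded from means.

The variable groups are **Onco** (origin, treatment history, spread, age),
**Path** (differentiation, grade, Ki-67, primary tumor), **Imm** (CK7, CK20,
TTF1, synaptophysin, chromogranin IHC) and **Lab** (serum markers and their
elevated/normal flags); the bench enumerates all 15 non-empty subsets.

## Consensus feature ranking

Per analysis level:

1. **Permutation importance (PI)** — for each fitted cell and feature, the
   mean decrease in test-set F1 over `n_perm` random permutations of that
   feature's column. Permutation is restricted to the test partition (no
   leakage); a feature's encoded value column and its missing-indicator are
   permuted jointly with one row permutation, which is equivalent to
   permuting the raw feature before encoding.
2. **Correlation filter** — features whose mean |PI| stays below
   `eps = 10⁻⁶` in every configuration are dropped; a lower-triangular
   feature–feature Spearman correlation matrix is emitted as a report
   artifact. The numeric drop rule is a package convention (the procedure it
   implements is described only qualitatively in the field).
3. **Stabilisation** — per configuration, |PI| is averaged over splits.
4. **Model weighting** — each configuration's mean F1 is divided by the mean
   F1 over all configurations, so weights average to 1 and stronger models
   count more.
5. **Aggregation** — `FI_f = Σ_m w_m · s_{m,f} / Σ_m w_m` over the
   configurations whose group subset contains f (coverage reported);
   reported FI is max-normalised to 1; rank ties break lexicographically.
6. **Selection** — the top `ceil(0.10 × retained)` features.
7. **Consensus** — features selected at *both* levels, ordered by the mean
   of the two normalised FI values, then confirmed statistically.

The exact functional form of step 5 is a declared convention (a
performance-weighted mean); whether selection happens before or after the
filter is likewise decided here (after).

## Statistical confirmation

Selected features are re-tested at α = 0.05, two-sided, without multiplicity
correction (a Benjamini–Hochberg flag exists, off by default). Lesion level:
the lesion-to-liver ratio is compared across feature groups — Mann–Whitney U
for binary or dichotomised features, Kruskal–Wallis for integer-valued
features with ≤ 4 levels. Numeric features are dichotomised at clinical
cut-offs (age 55 y; CEA 5, CA19-9 37, AFP 10, chromogranin A 100, NSE 16;
median split when no cut-off is configured). Patient level: eligibility ×
feature on a 2×2 table with Pearson's Chi-square, no continuity correction
(flag available). Exact Mann–Whitney p-values are used when both samples
have ≤ 8 observations and no ties; otherwise the tie-corrected normal
approximation with continuity correction. Missing values are excluded
pairwise; features with fewer than two observed levels are skipped with a
warning.

Note that lesion-level tests treat lesions as exchangeable even though
lesions of one patient share a latent uptake level; this mirrors the analysis
design the pipeline reproduces. The package's type-I calibration experiment
therefore uses one lesion per patient, where the tests' independence
assumption actually holds.

## The synthetic cohort generator

No real cohort is distributed, so every stage is exercised on a generator
that emulates the study's data structure:

* 65 patients (default), lesion count per patient `1 + Poisson(5.03)`
  (~392 lesions in expectation, every patient has at least one lesion);
* 100 patient-level and 104 lesion-analysis features (the four lesion-only
  slots are the metastasis-site indicators and lesion size), partitioned
  into the four groups; 29 structured features plus per-group noise fillers;
* latent patient log-uptake `μ_i = β₀ + Σ effect_f · x_{i,f} + N(0, 0.5)`
  with β₀ = 0.63 calibrated once so the default cohort reproduces the
  emulated frequencies (~50% of lesions grade 3–4, ~6% grade 2, eligible
  minority ≈ 0.32–0.40);
* each lesion draws one deviation `δ ~ N(0, 0.4)` shared by its two ratios:
  `ratio_liver = exp(μ + δ)`, `ratio_spleen = exp(μ + δ − 0.35)` — one
  lesion activity, two reference normalisations;
* planted effects (log-scale): CK7-positive −0.8, GI-tract origin +0.7,
  pancreatic origin +1.2, lung origin −0.8, NEC −0.9, prior oncological
  treatment −0.6. Tumor origin is encoded as disjoint one-hot levels
  (GI, pancreas, lung, unknown, other) so each planted effect is attached to
  an identifiable covariate — a nested "GEP ⊃ pancreas" encoding makes the
  pancreatic effect unidentifiable to permutation importance, which never
  sees off-manifold pancreas-without-GEP rows;
* missingness is injected completely at random at per-feature rates matching
  the emulated study's measurement frequencies (CK7 0.49, TTF1 0.57, CK20
  0.65, CEA 0.42, CA19-9 0.49, AFP 0.68, synaptophysin 0.17; noise features
  0.10); identifiers, ratios and outcomes are never masked;
* structured non-driver covariates (grade, Ki-67, labs) are generated with
  realistic marginals but only weak coupling to the planted drivers (labs
  load 0.2 on grade/origin; grade is drawn independently of the NEC flag).

The registry records each feature's role (`planted` / `structured` /
`noise`) so recovery experiments can score rankings against ground truth.

**What the generator does not emulate:** the joint distribution of a real
cohort — in particular the strong real-world confounding between grade,
Ki-67 and NEC status, non-random (retrospective) missingness, and any
image-derived noise structure. Passing recovery tests therefore shows the
pipeline identifies planted, identifiable signals under realistic sizes,
imbalance and missingness; it does not certify behaviour under heavy
covariate confounding, where permutation importance is known to dilute
credit across correlated proxies.

## Scale presets and problem sizes

The full protocol (100 splits × 100 permutations × 15 subsets × learners ×
two levels) is hours-scale; the `desk` preset is the tested default: 10
splits, 10 permutations, SMOTE on, 100 trees, linear baseline included, FI
computed from the two PRRT targets. The packaged experiments use: recovery —
20 replicate cohorts of 300 patients, reduced grid (boosted trees + SMOTE on
the full four-group subset), 10 splits, 20 permutations; group contrast —
150-patient cohorts, patient-grouped splits, Onco+Path+Imm vs Lab; null
calibration — 200 single-lesion 60-patient cohorts with all effects zero.

## Numerical conventions

* Mann–Whitney U is counted for the first sample (#(a > b) + half-ties),
  matching `scipy.stats.mannwhitneyu`.
* F1 with an empty denominator (no predicted and no true positives) is 0.
* Rank ties in the FI table break lexicographically by feature name; every
  random stream is seeded, and per-cell PI seeds derive from a CRC of the
  configuration id so results are independent of process hash salts.
* SMOTE reduces k with a warning when a minority class has fewer than k + 1
  members and raises on singleton classes.
* Degenerate statistical inputs: identical samples give p = 1; zero
  contingency margins raise; expected counts < 5 warn.

## Known limitations

* Lesion-level inference ignores within-patient clustering (by design, to
  mirror the reproduced analysis); effective sample sizes are smaller than
  row counts and row-wise splits allow patient memorisation — quantified and
  avoidable via the patient-grouped split option.
* Permutation importance dilutes credit across strongly correlated features;
  the generator deliberately limits such confounding (see above).
* The correlation-filter threshold and the FI functional form are package
  conventions; alternatives (e.g. rank-based aggregation) are not explored.
* No hyperparameter search, calibration, or survival modelling; the linear
  baseline is reported but never feeds the ranking.
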