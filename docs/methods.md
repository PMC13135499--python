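# Methods

This note documents the models and procedures implemented in `tabsafe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic fixtures do and do not demonstrate about real data.

## Preprocessing

**Model.** A cohort is a typed table: continuous columns (float), date
columns (calendar dates), binary/categorical columns (labels from a
declared vocabulary), identifier columns, with a single missing-value
token on disk (`n.a.` by default) and NaN/NaT in memory. The full
pipeline (variant `level3`) encodes it into a dense numeric matrix:

1. dates → signed day counts from a configurable reference date
   (default 2000-01-01, ISO-8601 only);
2. continuous/date columns → median imputation, then an empirical
   quantile transform; the imputation happens *before* the grid is
   fitted so that imputed cells land exactly on the median's grid point
   (this is what makes all median-imputed rows share one encoded value);
3. one binary missingness indicator per continuous/date column whose
   missing rate reaches `indicator_threshold`. The default threshold is
   0 — every such column gets a flag. Setting it to 0.5 reproduces the
   dimensionality-sparing policy of flagging only high-missingness
   columns, at the cost of lossy inversion for imputed cells of
   unflagged columns;
4. binary/categorical → one-hot with an explicit `Unknown` placeholder
   level for missing cells.

**Quantile dialect.** The i-th of n sorted observations receives level
(i − 0.5)/n; tied observations collapse to one grid point at the mean
of their levels. This keeps both grid axes strictly increasing (the map
is bijective on the grid), avoids exact 0/1 levels, and is symmetric.
Between grid points the map interpolates linearly; outside the grid it
clamps to the boundary levels. Output law is uniform on [0, 1] by
default with a Gaussian option (`output_distribution="normal"`).

**Inversion.** `inverse_transform` restores column names, order and
types: flags ≥ 0.5 restore missing cells (generative outputs need not
be binary), the one-hot argmax at the placeholder restores a missing
label, day counts round to the nearest day. Observed values round-trip
exactly because they are grid points; arbitrary encoded values invert
to within one grid-interpolation step. Identifier columns are excluded
from the encoded matrix — a model must never see record IDs — and are
regenerated as fresh sequential labels on inversion.

**Level-1/2 variant.** Missing continuous/date cells become the
constant −1 (passthrough scale, no flags); categoricals are one-hot as
above. Inversion maps −1 back to missing only when −1 was not an
observed value; otherwise the column is marked `lossy` in the transform
state and observed −1s are kept as-is rather than faking missingness.

## Auxiliary generative losses

With m encoded features, g the real and g̃ the generated pairwise
sample correlation matrices, and S_j⁽ʰ⁾, S̃_j⁽ʰ⁾ the order-h moments of
feature j:

* correlation loss: `L_cor = 2/(m(m−1)) · Σ_{j<k} (g_jk − g̃_jk)²`
* distribution loss:
  `L_dis = (1/m) Σ_j Σ_{h=1..H} (1/h) · (1 − (S̃_j⁽ʰ⁾+ε)/(S_j⁽ʰ⁾+ε))²`
* combined objective: `base + α·L_cor + β·L_dis`, with the base term
  supplied by whatever generator is being trained.

Choices: Pearson correlation on the encoded matrix (one-hot and flag
columns included) covers mixed types uniformly; Spearman is an option.
Moments are raw and computed on the encoded (quantile-scaled,
non-negative) features, because the ratio form is unstable around
zero-mean data; a central-moment option exists. Defaults H = 3,
ε = 1e−8, α = β = 1. When a denominator S_j⁽ʰ⁾ + ε is numerically zero
the term is clamped — to 0 if the numerator agrees, else to the
squared-unit penalty — with a runtime warning, so identical inputs
always score exactly 0.

Two reference generators make the losses exercisable without a deep
model. The copula baseline maps each real column to normal scores via
mid-ranks, samples a multivariate normal with the resulting correlation
(ridge-repaired if numerically degenerate), and maps back through each
column's empirical quantile function — preserving marginals and rank
correlations. The refiner perturbs random coordinate blocks of a
candidate sample with a decaying step and keeps a proposal only if
α·L_cor + β·L_dis does not increase; the objective trace is therefore
monotonically non-increasing. It is a stand-in for loss-guided
training, not a statement about how a real generator should optimise.

## Adaptive binning and total k-anonymity

All attributes are treated as simultaneously quasi-identifying and
sensitive. A binned table is *totally k-anonymous* when every nested
sequence of single-value filters over distinct columns yields, at every
step, either zero or at least k rows. Verification: a greedy test
repeatedly restricts the table to the globally rarest value and fails
on any count < k (a necessary condition — fast, one-sided); a greedy
pass is confirmed by an exhaustive recursive check with memoisation and
a configurable explored-state budget (default 10⁶) that raises rather
than silently passing when exceeded.

Adaptive binning starts every attribute at its finest hierarchy level;
while verification fails, the column holding the globally rarest value
is coarsened one level, or removed when no coarser level exists. Ties
in the rarest-value search break by column declaration order, then bin
label order, making outputs deterministic. Intervals are half-open
[lo, hi) throughout. Missing values form their own `missing` bin at
every level — dropping those rows would bias every count. Built-in
hierarchies: birth year (decades with adapted tails: <1940, 1940s,
1950s, 1960+; then <1950 / 1950+) and BMI (clinical classes:
underweight <18.5, normal [18.5, 25), overweight [25, 30), obesity
≥30; then normal− / overweight+ split at 25). Default k = 10: disclosed
aggregate counts are then provably 0 or ≥ 10 for every filter
conjunction.

## Disclosure-risk metrics

Distances are Euclidean on standardized encoded features;
standardization is fitted on the real table only. K-Means runs with a
fixed seed and 10 restarts over the granularity list {2, 5, 10, 15};
a granularity is unreliable (skipped, recorded in the report) when any
cluster is empty or holds fewer than 5 members, and if all are
unreliable the minimum non-empty occupancy is reported with a fallback
note.

* k-anonymity: minimum cluster occupancy (higher safer). l-diversity:
  minimum per-cluster count of distinct sensitive combinations. k-map:
  clusters fitted on real, synthetic assigned to the nearest centroid,
  minimum synthetic occupancy. Δ-presence: per corresponding cluster,
  the fraction of real sensitive combinations also present in the
  synthetic cluster (set-based), maximum over clusters; lower safer.
* Identifiability / single-out: fraction of real records strictly
  closer to some synthetic record than to their second-nearest other
  real record; ties count as not-closer. The two scores share one
  construction and are reported separately because they are tracked as
  distinct risks in release reports.
* Membership inference: the membership score of a record is its local
  density of synthetic points (inverse mean distance to the k nearest,
  k = ⌈√n_synth⌉ by default); AUC is the rank probability that a
  training record outscores a holdout record, accuracy thresholds at
  the median score. 0.5 ≈ no leakage.
* CAP: zero mode matches key attributes exactly; the attacker guesses
  the modal sensitive value of the matched synthetic set (deterministic
  lexical tie-break) and a record contributes 1 when the guess is
  correct, 0 otherwise (no match ⇒ 0). Generalized mode uses the
  nearest synthetic records in a pooled one-hot/standardized key space.
  Inference risk is generalized CAP for a declared known/secret split;
  with no known columns the best constant guess (synthetic modal class)
  is scored.
* Linkability: a real record is linked when its nearest synthetic
  record on feature subset A and on disjoint subset B is the same
  synthetic record, and that record's nearest real neighbour on A ∪ B
  is the original individual.
* Match rate: fraction of synthetic rows with at least one real row
  within the per-variable spans (days for dates, absolute for numerics,
  exact for categoricals) on *all* variables of a pseudo-identifier
  set; missing cells never match. The baseline repeats the procedure
  real-to-real excluding same-individual pairs. The shipped match
  configurations are illustrative defaults, not canonical.

## Evaluation and ranking

Column shapes: 1 − KS statistic (numeric/date, missing dropped
pairwise) or 1 − total variation distance (categorical, missing as its
own category). Pair trends: mean over pairs of 1 − |g − g̃|/2 on
encoded Pearson correlations (the /2 maps the maximal difference to
score 0). Quality = mean(column shapes, pair trends); diagnostic =
mean(validity, structure), both unweighted.

TSTR trains class-weighted logistic regression, linear SVM and
histogram gradient-boosted trees on synthetic rows and evaluates on
held-out real rows (weighted precision/recall/F1 and G-mean, the
geometric mean of per-class recalls, 0 when any class is fully
missed); the augmentation protocol reports the delta between real-only
and real+synthetic training. Hyper-parameters are library defaults.

Ranking: within-dataset ranks with ties averaged; the Friedman test via
the standard chi-square statistic; Nemenyi critical difference
CD = q_α·√(k(k+1)/(6N)) with q_α = q_{1−α}(k, ∞)/√2 taken from the
studentized-range distribution (no table needed; q_0.05(3)/√2 = 2.3437
reproduces the familiar tabulated 2.343). Failed (model, dataset) cells
receive the sentinel worst rank n_models + 1 (configurable — a field of
21 models would use 22) before averaging; family rank tables pool into
an overall table by stacking their per-dataset rank rows.

## Data sufficiency

The size grid starts at 1000 (configurable) and grows by 500 up to
5000, then by 5000 up to min(n_total, 70 000); the largest available
size is always included. For each size a seeded subsample is drawn, the
generator fitted, a same-size synthetic table scored; a generator
failure at one size records NaN rather than aborting the curve.

Knee detection fits a cubic smoothing spline (smoothing proportional to
the series variance; can be disabled) and applies the kneedle
procedure: normalise both axes to [0, 1], flip decreasing series and
convex curves so the knee is a maximum of the difference between the
curve and the chord, and accept the best interior local maximum only if
it beats sensitivity × mean x-spacing (sensitivity 1.0 by default). A
flat or straight series yields *no* knee — absence is reported, never
fabricated. The ranking route treats sizes as the treatments ranked
across (model, metric) blocks via Nemenyi average ranks; the composite
route min-max normalises each metric within declared (worst, best)
ranges — worst > best encodes lower-is-better, so improving any metric
never lowers the composite — and averages.

## Postprocessing

Row-level rules are implications (antecedent ⇒ consequent over
comparators ==, !=, <, ≤, >, ≥, in, not_in) and numeric ranges;
dependency rules (|corr − target| ≤ tol) are batch-level and re-checked
on the final accepted set, because per-row statistical acceptance is
not well-defined. A missing antecedent (or consequent) cell satisfies a
rule vacuously — rejecting on missing would silently bias missingness.
Each iteration requests the remaining deficit divided by the observed
acceptance rate (floored at 0.1, capped at 10× the target) so the
iteration count stays bounded; an unreachable target raises with the
partial log attached. Rules enter through the config, never derived
from the real records, so the step does not touch private training data
and leaves any formal privacy guarantee of the generator intact.

## Fixtures: what they show and what they don't

The fixture generator draws correlated anthropometric and blood
measurements from a Gaussian copula with declared marginals (normal or
log-normal), derives BMI exactly as weight/height², samples dates
uniformly in declared ranges, assigns smoking status and a multiclass
cancer label with sex-specific admissibility (and a smoking-dependent
lung-cancer relative risk of 4), and injects MCAR or MAR missingness
per column. Default missingness spans 0.4%–90% across columns,
matching the envelope seen in real biobank extracts. MAR is a
per-stratum deletion probability keyed by a conditioning column.

Passing tests on these fixtures demonstrate correctness of the
machinery — invertibility, verification soundness, metric calibration
against planted constructions — under known, well-behaved generative
structure. They do not demonstrate that any particular generator
produces safe or faithful synthetic data for a real cohort: real data
have heavier tails, structured missingness beyond single-column MAR,
longitudinal dependence and hundreds of columns, none of which the
fixtures emulate.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
cohorts of 60–5000 rows, brute-force verification on tables up to ~400
rows and 6 columns, O(n²) distance oracles up to 50 rows. The
brute-force recursion memoises on (row set, remaining columns) and is
intended for verification of binned (low-cardinality) tables, not raw
data. Degenerate inputs are handled explicitly: constant columns
correlate as 0 by convention; empty synthetic tables are guarded;
all-missing columns are an error in fitting; k-means granularities
larger than the table are skipped.

## Known limitations

* No deep generative models ship with the package; the copula baseline
  underestimates what a trained model can leak, so privacy scores on it
  are a lower bound on risk, not a clearance.
* No formal (ε, δ) differential-privacy accounting — the metric suite
  is empirical.
* The identifiability and single-out scores are intentionally the same
  construction; any distance-weighted variant would need to be added
  explicitly.
* Generalized CAP's key space mixes standardized numerics with one-hot
  categoricals; the implied trade-off between a unit of numeric
  distance and a category mismatch is a modelling choice.
* The brute-force anonymity check is exponential in the worst case;
  the state budget makes failure explicit rather than cheap.
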