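# Methods

This note documents the models implemented in `thermotactics`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions adopted where the underlying
methodology leaves room.

## Temporal eigenfunction basis

Hourly body-temperature series on a shared regular grid of `n` samples are
modelled on the sinusoidal eigenfunction basis

    E_k(i) = sin(k π i / (n + 1)),   i = 1..n,   k = 1..K,

whose columns are exactly orthogonal on the complete grid. The period of
harmonic `k` is taken as `2n/k` hours: the half-cycle of `E_1` spans the
whole window, and with the study-scale defaults (`n = 450`, `K = 205`)
this mapping places exactly 25 harmonics above the 35 h broad-band cut
(harmonic 25 → 36.0 h, harmonic 26 → 34.6 h), puts harmonic 36 at the
diel anchor of 25 h, and ends at 4.39 h for harmonic 205. The four default
scale bands are fixed index ranges — broad 1–25, diel 26–62, crepuscular
63–87, fine 88–K — rather than being recomputed from the period mapping,
because no single linear mapping reproduces every printed band boundary;
the fixed ranges are the partition actually used for classification.

**Moran filter.** Only eigenfunctions with positive, significant temporal
autocorrelation are candidate predictors. Moran's I is computed against
binary lag-1 contiguity (`w_ij = 1` iff `|i−j| = 1`, row-unstandardized),
with the analytic randomization-variance normal approximation and a
one-sided test (`H1: I > −1/(n−1)`) at α = 0.05. A permutation version
would add cost without changing any decision, since the basis is
deterministic. On the 450-sample grid all 205 harmonics pass. One
empirical caveat, verified against a brute-force double-loop oracle: I
decreases monotonically in `k` only from `k = 2`; the half-wave `E_1` has
a mean far from zero, and mean-centring lowers its lag-1 autocorrelation
slightly below that of harmonic 2. The filter is unaffected (both pass
easily), but monotonicity should not be assumed at `k = 1`.

**VIF pruning.** Missing observations break the orthogonality of the
basis restricted to observed rows, so before each per-fish regression the
design is pruned by iteratively removing the column with the largest
variance inflation factor until all VIFs are ≤ 10 (ties resolved toward
the higher harmonic index, preserving coarser scales). The VIF is computed
*uncentered* — from the inverse cosine matrix of the norm-scaled raw
columns, equivalently intercept-free auxiliary regressions. This is a
deliberate choice: on the complete grid the raw sine columns are exactly
orthogonal, so every uncentered VIF is exactly 1 and any flagged
collinearity is a pure missing-data artifact, which is the stated purpose
of the step. The textbook centred VIF would instead flag the low odd
harmonics as collinear with the constant even on complete data (centred
VIF of `E_1` is ≈ 368 at `K = 205`), because the constant vector is well
approximated by the odd harmonics; that would delete the broadest scale
from every fit regardless of the data.

## Per-fish fits and the partial-R²adj scalogram

Each fish's series is fit by OLS with intercept on the retained,
VIF-pruned eigenfunctions, using observed rows only (listwise deletion; no
imputation). The fit requires at least 10 more observations than
predictors. The full-model adjusted R² is
`1 − (1 − R²)(n_obs − 1)/(n_obs − p − 1)`.

**Partial R²adj.** The contribution of eigenfunction `k` is defined by
allocating the full model's adjusted R² (floored at 0) across predictors
in proportion to their leave-one-out SSE increments — the rise in residual
sum of squares when that predictor alone is removed and the model refit on
the same rows, available in closed form as `β_k² / [(X'X)⁻¹]_kk`. This
definition was chosen over the raw drop in adjusted R² on deletion
because the raw drop does not sum to the full-model R²adj (with `p = 205`
predictors the refit-without model's adjustment term shifts by a factor
`(n−p)/(n−p−1)` per deletion, so raw drops can exceed 1), whereas the
allocation is exact by construction: contributions are nonnegative, sum to
the floored R²adj, and on a complete (orthogonal) grid reduce to each
harmonic's variance share rescaled to the adjusted scale.

One attribution is intrinsically ill-posed: a signal shaped exactly like
`E_1`. Given the intercept and the other odd harmonics, `E_1` is nearly
reconstructable (residual norm ≈ 0.7 of its ≈ 15 raw norm at `K = 205`),
so its unique contribution is tiny and, under noise, is scrambled across
the low odd harmonics. Band totals are robust to this — all of the
scrambling stays inside the broad band — but single-harmonic attribution
at the very lowest frequencies should not be over-read. The synthetic
broad-scale component is therefore anchored at 300 h (harmonic 3), where
attribution is stable.

The population scalogram reports the mean and sample SD of the partial
vectors across individuals, ordered by decreasing period; a single
individual yields SD 0 with a warning.

## Tactic classification

Cumulative partial R²adj over the four bands forms a nonnegative
individuals × 4 matrix. Rows are Hellinger transformed
(`sqrt(x_ij / Σ_j x_ij)`; unit sum of squares per row), which removes each
individual's overall fit quality and leaves its *composition* across
temporal scales. A covariance PCA (not correlation — the Hellinger
transform already normalizes rows; this is standard transformation-based
ordination) yields scores and loadings. Axes are sign-fixed: axis 1 so the
broad-band loading is positive, axis 2 so the summed crepuscular + fine
loading is positive; an exactly zero orienting loading leaves the axis
as computed with a warning. Quadrants of the oriented plot define the
tactics — axis 1 negative: diel side (I above, IV below the axis-2 zero);
axis 1 positive: broad side (II above, III below) — and the pooled
I/IV vs II/III dichotomy follows the sign of axis 1 alone. A score of
exactly zero is resolved toward the positive side and flagged, so the
zero-measure case is still deterministic.

## Lake layers and epilimnion occupancy

For each hourly thermograph column the downward gradient of each 0.5 m
interval is converted to °C/m; the metalimnion is the shallowest maximal
contiguous run of intervals steeper than 1 °C/m, the epilimnion everything
above its top. Daily summaries pool all observed (depth, hour) cells per
layer over the day's stratified hours and report median boundary depths;
days with no stratified hour are omitted with a warning.

Transmitters report temperature, not depth, so epilimnion occupancy of a
fix is inferred by temperature matching: a fix is epilimnetic when the
body temperature is at least the hour's minimum epilimnion temperature
minus a 0.5 °C tolerance, which absorbs the ~20 min thermal equilibration
of implanted transmitters. Occupancy is undefined (an error, and the fix
is excluded from that day's excursion percentage) in unstratified hours.

## Excursion threshold tree

The daily excursion frequency (percent of a fish-day's defined fixes in
the epilimnion) is modelled by a least-squares binary regression tree on
mean daily epilimnion temperature, mean daily metalimnion temperature, day
of year, and year.

* **Split search** is exhaustive: candidate thresholds are midpoints
  between consecutive distinct predictor values; the split maximizing the
  SSE reduction wins, with ties resolved by column order and then by the
  smaller threshold. A fast prefix-sum scan shortlists near-tied
  candidates, which are re-scored by direct SSE computation, so the grown
  tree is bit-reproducible and exactly equal to a naive exhaustive search.
* **Stopping**: a split must reduce SSE by at least `cp = 0.01` of the
  root SSE and leave at least `min_leaf = 5` observations per child.
* **Cost-complexity sequence**: weakest-link pruning generates the nested
  subtree sequence used for cross-validation.
* **Unit-blocked 10-fold CV**: fish are the sampling units; units are
  shuffled with the run seed and dealt round-robin into folds, so every
  observation of a fish shares its fold and held-out fish are predicted
  only from other fish. Candidate penalties are geometric means of
  adjacent critical alphas, rescaled to each training fold's root SSE.
  The CV error of a candidate is the mean over folds of the held-out SSE
  relative to the full response's root SSE; its SE is the standard error
  of that mean across folds.
* **1-SE pruning** selects the smallest subtree whose CV error is within
  one SE (at the minimizer) of the minimum.
* **Permutation test**: whole response blocks are reshuffled among units
  of equal size (preserving within-fish correlation under the null), a
  tree of the observed leaf count is grown best-first (always splitting
  the leaf with the largest SSE reduction — identical to CART at the
  2-leaf complexity, and the maximal-achievable count is used if a
  permuted response cannot support the observed complexity), and
  `p = (#{null R² ≥ observed} + 1)/(m + 1)` with `m = 999` by default.
  Block-level shuffling, rather than per-observation shuffling, is the
  same design principle as the unit-blocked CV: the exchangeable units
  are fish, not fish-days.

Horizontal movement is summarized as straight-line (planar UTM; no
geodesic correction at lake scale) distances between consecutive fixes,
labelled by arrival period, and tabulated as mean/SD/count per period ×
thermal condition (epilimnion above/below a caller-supplied threshold,
typically the fitted root split).

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, at desk scale, all bit-reproducible under a seed.

* **Lake** (`simulate_lake`): logistic vertical profile between a 6 °C
  hypolimnion and a ~23 °C surface (seasonal ramp ±0.75 °C, diurnal
  sinusoid ±0.8 °C peaking in late afternoon), depths 0–10 m at 0.5 m,
  hourly. Every hourly column is stratified and daily epilimnion minus
  metalimnion means exceed 5 °C, the mid-summer regime of a small
  temperate oligotrophic lake.
* **Fish series** (`simulate_fish_series`): baseline 16 °C plus
  seeded-phase sinusoids per tactic — I: 24 h/1.2 °C + 12 h/1.0 +
  8 h/1.0; II: 300 h/1.2 + 12 h/1.0 + 8 h/1.0; III: 300 h/1.8;
  IV: 24 h/1.8 — plus AR(1) noise (coefficient 0.6, marginal SD 0.3 °C,
  mimicking body-temperature inertia rather than white measurement
  noise). Exactly `round(rate · n)` hours are removed completely at
  random, with per-fish rates drawn uniformly from the 9–35 % envelope
  observed in field telemetry. Dropout is MCAR only, since receiver
  malfunction, not behaviour, drives missingness in such studies.
* **Telemetry** (`simulate_telemetry`): 4 fixes per fish-day
  (dawn/day/dusk/night) from a random walk with gamma step lengths whose
  mean drops from 150 m to 60 m on days whose epilimnion mean exceeds
  22.4 °C.
* **Excursion tables** (`simulate_excursion_dataset`): fish-day records
  with epilimnion means uniform on 20–26 °C and metalimnion means on
  10–15 °C, generative cell means 1 % (warm epilimnion), 40 % (cool
  epilimnion, metalimnion > 12 °C) and 10 % (both cool), Gaussian noise
  (SD 5 points) clipped to [0, 100], an optional per-fish random
  intercept for unit-correlated designs, and staggered per-fish tracking
  windows (up to 20 days of offset) emulating staggered tagging.

What the generators do **not** emulate: spatial heterogeneity of the lake
(all fish see the same profile), behaviourally driven missingness,
interactions between tactic and movement, drifting periodicities or phase
inversions within a fish, and measurement error on positions. Passing the
recovery tests therefore shows the estimators recover the structure they
target under realistic noise and missingness — not that every feature of
field data is handled.

## Verification problem sizes

The verification suite and `scripts/acceptance.py` use: 50 random
instances (n ≤ 200) for exact tree-oracle equality; 100 replicates of
single-harmonic recovery (harmonics 2–205, amplitude 2 °C, noise SD
0.5 °C, 9–35 % MCAR); 20 replicate 16-fish populations for pooled-tactic
recovery; 20 seeds of 1 000 fish-days for 22.4 °C threshold recovery
(tolerance ±0.2 °C); 500 repetitions (99 permutations each, 16 fish × 8
days, fish-effect SD 8, noise SD 5) for the permutation test's type-I
error at α = 0.05; and 20 replicates comparing unit-blocked with naive
10-fold CV on unit-correlated null data.

## Known limitations

* Harmonic-level attribution near `E_1` is ill-posed (see above); the
  scalogram's broad-band *total* is the trustworthy quantity there.
* The adjusted R² of a 205-predictor null fit has a sampling SD of ≈ 0.06
  at n = 450, so individual noise fits can show |R²adj| up to ≈ 0.2;
  only its expectation is near zero.
* The equal-size constraint of the unit-block permutation scheme requires
  a balanced design (or permutes only within size classes, reducing the
  effective permutation space for very unbalanced studies).
* Layer detection assumes a single thermocline; double-stratified columns
  resolve to the shallowest steep run by convention.
* Period-of-day labels are taken from the input, not recomputed from
  solar events, and timestamps are treated as a single local timezone.
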