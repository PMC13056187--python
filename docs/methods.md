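# Methods

This note records the model, the estimation procedure, every user-facing
parameter with its default and rationale, what the synthetic generator does
and does not emulate, and the numerical choices made in the implementation.

## 1. Data model

A study is a `StudyDataset` of three tables plus a distance matrix:

- **demand** — one row per demand site (block group): `lat`, `lon` (decimal
  degrees, WGS84-style), `population` (persons, ≥ 0), optional covariates
  (`income`, `region_id`).
- **supply** — one row per supply site (hospital): `lat`, `lon`,
  `capacity` (service units, e.g. licensed beds, > 0).
- **flows** — observed origin–destination visit counts: `demand_id`,
  `supply_id`, `visits` (> 0; duplicate pairs are summed, zero rows dropped).

Distances are great-circle (haversine) on a sphere of mean radius
**3,958.8 miles**, floored at **0.1 mi** (`DEFAULT_DISTANCE_FLOOR`). The floor
exists because the power-law kernel d^β diverges as d → 0 for β < 0; 0.1 mi
is below any meaningful centroid-to-facility separation at block-group scale,
so the floor only regularizes coincident-coordinate pairs.

## 2. Catchment-assumption diagnostics

For facility *j* with visits w_ij from origins at distances d_ij:

- **VWAD_j** = Σ_i w_ij d_ij / Σ_i w_ij — visit-weighted average distance,
  the empirical catchment radius (miles). VWAD_i is defined symmetrically
  per demand site over the facilities it visits.
- **RWD** = VWAD divided by the unweighted mean distance to *all*
  counterparts in the study. RWD ≈ 1 means visits ignore distance; RWD ≪ 1
  means realized interaction is far more local than geography alone implies.
- **HosCovRatio_j** = (number of origins with positive flow to *j*) / (total
  number of block groups); **PopChoiceRatio_i** = (number of facilities
  visited from *i*) / (total number of facilities).

Entities with zero total flow get NaN VWAD/RWD and are excluded from the
summary means (but counted in the entity totals).

## 3. Per-facility decay calibration

Each facility's visitation profile is the set of (d_ij, ω_ij) pairs over
origins with positive flow (ω = visit count). Two kernels are fitted by OLS
**on the shared response ln ω**, which makes their R² and AIC directly
comparable:

| form        | model                | regression          |
|-------------|----------------------|---------------------|
| power law   | ω = α·d^β            | ln ω ~ ln d         |
| exponential | ω = α·e^(β·d)        | ln ω ~ d            |

**Sign convention.** `beta` is stored as the fitted slope, so decay means
β < 0, and downstream weights are always evaluated as α·d^β (or α·e^(β·d)).
No sign flip is applied anywhere.

**AIC.** Gaussian-likelihood form AIC = n·ln(RSS/n) + 2k with k = 2
parameters, i.e. n·ln(RSS/n) + 4; −∞ when RSS = 0 (exact fit). Constant
responses (all ω equal) are defined to have R² = 0 and slope p = 1.

**Classification** (`classify_decay`): a form wins outright when it beats the
other on both R² and AIC (AIC margin > `delta_aic_threshold`, default **2.0**
— the conventional "substantial support" cutoff) *and* its slope is
significantly negative (one-coefficient p < `alpha_level`, default **0.05**).
Without an outright winner, a single significantly decaying candidate wins;
otherwise the facility is classified `"none"` (no clear decay, parameters
NaN). Facilities with fewer than `min_points` = **3** positive-flow origins
(a two-parameter fit needs at least three points) or zero distance variance
are marked unfittable.

## 4. Accessibility models

**Traditional (stepwise) E2SFCA**, `TraditionalConfig`: zone breakpoints
(10, 20, 30) miles with weights (1.0, 0.68, 0.22) — the customary gravity-
motivated three-zone schedule; beyond the last breakpoint the weight is 0.

Step 1: R_j = S_j / Σ_i W(d_ij)·P_i; Step 2: A_i = Σ_j W(d_ij)·R_j.
With a single all-covering zone of weight 1 this model conserves supply
exactly: Σ_i P_i·A_i = Σ_j S_j (tested to machine precision).

**Revised E2SFCA**, `revised_e2sfca`:

- Catchments are entity-specific: facility *j* draws demand from
  {i : d_ij ≤ VWAD_j}; demand site *i* reaches {j : d_ij ≤ VWAD_i}
  (`resolve_catchments`; entities without flows fall back to the median VWAD
  by default, or a global radius; radii are floored at `min_radius` = 0.1 mi).
- Step 1 weights are the facility's own calibrated kernel:
  WeightedDemand_j = Σ_i α_j·d_ij^{β_j}·P_i, R_j = S_j / WD_j.
- `resolve_decay_parameters` turns calibrations into per-facility (α, β).
  With `force_power_law=True` (default) every facility uses its power-law
  fit regardless of classification, so Step 1 is uniformly defined;
  unfittable facilities get the median power-law parameters.
- Step 2 default is `step2_weighting="ratio_sum"`: A_i = Σ_j R_j over the
  demand site's catchment — the ratios are summed unweighted. The
  alternative `"weighted_sum"` applies the facility kernels again in Step 2
  (A_i = Σ_j α_j·d_ij^{β_j}·R_j), restoring the classic E2SFCA symmetry at
  the cost of double-counting decay. `ratio_sum` does **not** conserve
  supply (a unit test exhibits a counterexample); this is a property of the
  model, not a bug.

Scores have units of capacity per person; `minmax_normalize` maps any score
vector to [0, 1] (constant vectors map to zeros with a warning).

## 5. Validation statistics

- **Pearson r** between score surfaces (scipy.stats.pearsonr).
- **Gini index** over the population distribution of scores, computed with
  the sorted-rank identity G = Σ_k (2k − n − 1)·x_(k) / (n·Σ x); for
  nonnegative data G ∈ [0, (n−1)/n]. Higher Gini = the model reveals more
  inequality in access.
- **Global Moran's I** with row-standardized k-nearest-neighbor weights
  (default k = **8** — the common "queen-like" neighborhood size for point
  supports; a distance-band alternative is available), expected value
  −1/(n−1), and a two-sided permutation pseudo p-value
  p = (1 + #{|I*| ≥ |I_obs|}) / (1 + permutations), default **999**
  permutations. Lower I = less spatially smoothed surface.
- **Multivariate OLS** of scores on covariates (statsmodels), with a design-
  rank check.

## 6. Synthetic generator

`generate_scenario(ScenarioConfig)` draws, from a single seeded
`numpy.random.Generator`:

1. Facility locations uniform in the bounding box; block groups partly
   **clustered around facilities** (`demand_cluster_fraction`, Gaussian
   jitter `demand_cluster_sigma_deg` latitude, 1.3× that in longitude to be
   roughly isotropic in miles) and partly uniform. Clustering emulates urban
   cores, which concentrate both population and facilities and provide the
   short-distance observations where the two kernels actually differ.
2. Log-normal populations, incomes, and capacities; grid-cell region ids.
3. Per-facility ground truth: form (power with probability
   `power_fraction`), slope β uniform in the form's range, amplitude α
   log-normal, truncation radius uniform in `catchment_radius_range`.
4. Poisson flows: λ_ij = `visit_scale` · (P_i / mean P) · f_j(d_ij) ·
   1[d_ij ≤ radius_j], w_ij ~ Poisson(λ_ij); zero counts are dropped.

Key defaults (`ScenarioConfig`): populations log-normal(6.9, 0.5) (median
≈ 1000 persons, block-group scale), capacities log-normal(5.0, 0.7) (median
≈ 150 beds), α log-normal(3.66, 0.86) (median ≈ 39, right-skewed), power
slopes in (−0.45, −0.10), exponential slopes in (−0.08, −0.02) per mile,
radii 20–80 mi.

Presets: **mixed_pa_like** (1500 block groups, 40 hospitals, 60% clustered
demand, radii 25–90 mi — a mixed-regime statewide panel at a size where each
facility sees a few hundred origins), **localized** (steep decay, tight
radii: RWD ≪ 1), **dispersed** (near-flat decay, no effective truncation:
RWD ≈ 1). `recovery_benchmark_config` is a separate benchmark for parameter
recovery: compact box, no truncation, steeper well-separated slope ranges,
visit scale 50, chosen a priori so both forms are identifiable and
classification accuracy can be measured against ground truth.

**What the generator does not emulate:** real road-network travel times
(distances are great-circle), capacity constraints and congestion feedback
(flows are independent Poisson draws, not a constrained assignment),
insurance/referral networks, temporal variation, within-block-group
population structure, and correlated measurement noise in mobility panels.
Benchmark results on it measure algorithmic correctness and statistical
identifiability, not real-world predictive validity.

## 7. Numerical choices

- Distances, Step-1/Step-2 accumulations, diagnostics, and the generator are
  fully vectorized in numpy; tests check them against independent
  double-loop brute-force oracles at rtol 1e-9.
- OLS goes through statsmodels; Pearson through scipy; kNN through
  scipy.spatial.cKDTree. Gini, Moran's I, haversine, and both FCA
  accumulations are implemented here and oracle-tested.
- All stochastic code takes explicit seeds; `scripts/acceptance.py` derives
  sub-seeds from `--seed` via `numpy.random.SeedSequence` (reduced mod 2³¹).

## 8. Limitations

- The revised model's `ratio_sum` Step 2 is not supply-conserving; compare
  models on relative, not absolute, terms.
- Log-OLS on counts is biased for low counts (Jensen's inequality) and
  requires ω > 0, so zero-flow pairs carry no information about decay tails.
- Classification power depends on the distance support: without
  short-distance observations the power and exponential kernels are nearly
  collinear and many facilities classify as "no clear decay" — a finding,
  not a failure.
- VWAD-based catchments are endogenous to the observed flows: sparse or
  censored panels shrink catchments and can understate access.
- The permutation test for Moran's I assumes exchangeability under the null;
  heteroskedastic surfaces can inflate the pseudo p-value's sharpness.
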