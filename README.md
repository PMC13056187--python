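# flowcatch

Mobility-driven floating catchment accessibility modeling.

## The problem

The Enhanced Two-Step Floating Catchment Area (E2SFCA) method is the standard
way to measure spatial accessibility to healthcare. It assigns each facility a
supply-to-demand ratio over the population inside a fixed catchment (Step 1),
then sums those ratios over the facilities reachable from each neighborhood
(Step 2), discounting by distance with a stepwise weight schedule. Its two
structural assumptions — one catchment radius for everybody, and one
universal distance-decay curve — are convenient, but observed patient travel
contradicts both: facilities differ enormously in how far their visitors come
from, and the shape of distance decay varies facility by facility.

`flowcatch` implements a revised E2SFCA that replaces both assumptions with
quantities estimated from an observed origin–destination visit panel
(e.g., aggregated mobility flows from block groups to hospitals):

1. **Diagnostics** quantify how badly the fixed-catchment assumptions fail:
   per-facility and per-neighborhood visit-weighted average distance (VWAD),
   relative weighted distance (RWD = VWAD divided by the unweighted mean
   distance to all counterparts), and coverage/choice ratios.
2. **Calibration** fits, for every facility *j*, two candidate decay kernels
   to its visitation profile ω(d) by OLS on ln ω —
   a power law ω = α·d^β and an exponential ω = α·e^(β·d) — and classifies
   each facility to the form that wins on both R² and AIC with a
   significantly negative slope (otherwise "no clear decay").
3. **Accessibility** recomputes E2SFCA with facility-specific catchments
   (radius = that facility's VWAD) and facility-specific decay weights:

   Step 1: R_j = S_j / Σ_{i: d_ij ≤ VWAD_j} α_j·d_ij^{β_j}·P_i

   Step 2: A_i = Σ_{j: d_ij ≤ VWAD_i} R_j

   The classic stepwise-zone E2SFCA is included as the baseline.
4. **Validation** compares the two score surfaces: Pearson correlation,
   population Gini index (how much inequality each model reveals), Global
   Moran's I with permutation inference (how spatially smoothed each surface
   is), and multivariate OLS against covariates.
5. A **synthetic generator** produces origin–destination panels from a
   gravity model with known per-facility ground truth (form, α, β, catchment
   radius), so the whole pipeline can be benchmarked for parameter recovery.

## Worked example

```python
from flowcatch import (scenario_presets, generate_scenario, interaction_summary,
                       calibrate_hospitals, TraditionalConfig, traditional_e2sfca,
                       resolve_decay_parameters, resolve_catchments, revised_e2sfca,
                       gini_index, morans_i)

cfg = scenario_presets("mixed_pa_like", seed=7)       # 1500 block groups, 40 hospitals
dataset, truth = generate_scenario(cfg)
print(f"{dataset.n_demand} block groups, {dataset.n_supply} hospitals, "
      f"{len(dataset.flows)} origin-destination flow pairs")

diag = interaction_summary(dataset)
print(f"mean VWAD (hospital perspective):    {diag.summary['mean_vwad_hospital']:.1f} mi")
print(f"mean VWAD (block-group perspective): {diag.summary['mean_vwad_blockgroup']:.1f} mi")
print(f"mean PopRWD: {diag.summary['mean_poprwd']:.2f}")

calibrations, cal = calibrate_hospitals(dataset)
print(f"classified power-law: {100*cal.frac_power:.0f}%   "
      f"exponential: {100*cal.frac_exponential:.0f}%   "
      f"no clear decay: {100*cal.frac_none:.0f}%")
print(f"median fitted beta: {cal.median_beta:.2f}   mean R^2: {cal.mean_r2:.2f}")

traditional = traditional_e2sfca(dataset, TraditionalConfig())
decay = resolve_decay_parameters(calibrations, dataset.supply.index)
catchments = resolve_catchments(dataset)              # per-entity VWAD radii
revised = revised_e2sfca(dataset, decay, catchments)

coords = dataset.demand[["lat", "lon"]].to_numpy()
for name, s in (("traditional", traditional), ("revised", revised)):
    x = s.scores.to_numpy()
    m = morans_i(x, coords, k=8, permutations=999, seed=1)
    print(f"{name:>11}:  Gini = {gini_index(x):.3f}   "
          f"Moran's I = {m.I:.3f} (p = {m.p_perm:.3f})")
```

Output:

```
1500 block groups, 40 hospitals, 10054 origin-destination flow pairs
mean VWAD (hospital perspective):    28.1 mi
mean VWAD (block-group perspective): 33.9 mi
mean PopRWD: 0.28
classified power-law: 45%   exponential: 30%   no clear decay: 25%
median fitted beta: -0.29   mean R^2: 0.22
traditional:  Gini = 0.388   Moran's I = 0.926 (p = 0.001)
    revised:  Gini = 0.456   Moran's I = 0.761 (p = 0.001)
```

A mean PopRWD of 0.28 says realized visits travel less than a third of the
distance a uniform-catchment model assumes. The revised model reveals more
inequality (higher Gini) and a less spatially smoothed surface (lower
Moran's I) than the stepwise baseline — the baseline's shared zones and
weights smear local differences away.

## Command-line interface

Every stage is also a `flowcatch` subcommand working on CSV files
(`demand.csv`, `supply.csv`, `flows.csv` with columns documented in
`flowcatch simulate --help` output files):

```sh
flowcatch simulate --preset mixed_pa_like --seed 7 --out-dir study/
flowcatch diagnose  --demand study/demand.csv --supply study/supply.csv \
                    --flows study/flows.csv --out study/diagnostics.csv
flowcatch calibrate --demand study/demand.csv --supply study/supply.csv \
                    --flows study/flows.csv --out study/decay.csv
flowcatch access    --demand study/demand.csv --supply study/supply.csv \
                    --flows study/flows.csv --method revised --out study/scores.csv
flowcatch validate  --demand study/demand.csv --supply study/supply.csv \
                    --flows study/flows.csv --out study/validation.json
flowcatch run       --config run.yaml          # whole pipeline + provenance.json
```

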