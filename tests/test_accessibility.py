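import numpy as np
import pandas as pd
import pytest

from flowcatch.accessibility import (CatchmentSpec, DecayParameterSet,
                                     TraditionalConfig, minmax_normalize,
                                     resolve_catchments, resolve_decay_parameters,
                                     revised_e2sfca, traditional_e2sfca)
from flowcatch.decay import calibrate_hospitals
from flowcatch.diagnostics import interaction_summary
from flowcatch.errors import ConfigurationError, DegenerateInputError

from conftest import dataset_from_distances, random_dataset


def make_decay(supply_index, forms, alphas, betas):
    table = pd.DataFrame({"form": forms, "alpha": alphas, "beta": betas,
                          "fallback": False}, index=supply_index)
    return DecayParameterSet(table=table)


def global_catchments(ds, radius=1e9):
    return CatchmentSpec(
        supply_radii=pd.Series(radius, index=ds.supply.index),
        demand_radii=pd.Series(radius, index=ds.demand.index))


def brute_force_traditional(ds, config):
    """Independent double-loop stepwise E2SFCA."""
    D, P = ds.distances.values, ds.demand["population"].to_numpy()
    S = ds.supply["capacity"].to_numpy()

    def weight(d):
        for bp, w in zip(config.breakpoints, config.weights):
            if d <= bp:
                return w
        return 0.0

    R = np.zeros(len(S))
    for j in range(len(S)):
        denom = sum(weight(D[i, j]) * P[i] for i in range(len(P)))
        R[j] = S[j] / denom if denom > 0 else 0.0
    A = np.array([sum(weight(D[i, j]) * R[j] for j in range(len(S)))
                  for i in range(len(P))])
    return A, R


def brute_force_revised(ds, decay, catchments, step2):
    """Independent double-loop dynamic-catchment accumulation."""
    D, P = ds.distances.values, ds.demand["population"].to_numpy()
    S = ds.supply["capacity"].to_numpy()
    tab = decay.table.loc[ds.supply.index]
    rj = catchments.supply_radii.loc[ds.supply.index].to_numpy()
    ri = catchments.demand_radii.loc[ds.demand.index].to_numpy()

    def f(j, d):
        a, b = tab["alpha"].iloc[j], tab["beta"].iloc[j]
        return a * d ** b if tab["form"].iloc[j] == "power" else a * np.exp(b * d)

    R = np.zeros(len(S))
    for j in range(len(S)):
        wd = sum(f(j, D[i, j]) * P[i] for i in range(len(P)) if D[i, j] <= rj[j])
        R[j] = S[j] / wd if wd > 0 else 0.0
    A = np.zeros(len(P))
    for i in range(len(P)):
        for j in range(len(S)):
            if D[i, j] <= ri[i]:
                A[i] += R[j] if step2 == "ratio_sum" else f(j, D[i, j]) * R[j]
    return A, R


class TestTraditional:
    def test_hand_computed_single_hospital(self):
        # S=10, P=(100, 300), zone weights (1.0, 0.5): R = 10/250, A = (0.04, 0.02)
        ds = dataset_from_distances([[5.0], [15.0]], [100, 300], [10], [])
        config = TraditionalConfig(breakpoints=(10.0, 20.0), weights=(1.0, 0.5))
        scores = traditional_e2sfca(ds, config)
        assert scores.supply_ratio["h0"] == pytest.approx(0.04)
        assert scores.scores["bg0"] == pytest.approx(0.04)
        assert scores.scores["bg1"] == pytest.approx(0.02)

    def test_everything_out_of_range_scores_zero(self):
        ds = dataset_from_distances([[50.0], [70.0]], [100, 300], [10], [])
        scores = traditional_e2sfca(ds, TraditionalConfig((10.0,), (1.0,)))
        assert (scores.scores == 0).all()

    def test_conservation_with_single_covering_zone(self):
        rng = np.random.default_rng(14)
        ds = random_dataset(rng)
        scores = traditional_e2sfca(ds, TraditionalConfig((1e9,), (1.0,)))
        lhs = float((ds.demand["population"] * scores.scores).sum())
        rhs = float(ds.supply["capacity"].sum())
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            TraditionalConfig((20.0, 10.0), (1.0, 0.5))
        with pytest.raises(ConfigurationError):
            TraditionalConfig((10.0, 20.0), (0.5, 1.0))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(15)
        ds = random_dataset(rng)
        config = TraditionalConfig()
        scores = traditional_e2sfca(ds, config)
        A, R = brute_force_traditional(ds, config)
        np.testing.assert_allclose(scores.scores.to_numpy(), A, rtol=1e-9)
        np.testing.assert_allclose(scores.supply_ratio.to_numpy(), R, rtol=1e-9)


class TestRevised:
    def test_hand_computed_single_hospital(self):
        # alpha=1, beta=-1: WD = 0.5*100 + 0.25*300 = 125; R = 0.08
        ds = dataset_from_distances([[2.0], [4.0]], [100, 300], [10], [])
        decay = make_decay(ds.supply.index, ["power"], [1.0], [-1.0])
        scores = revised_e2sfca(ds, decay, global_catchments(ds))
        assert scores.weighted_demand["h0"] == pytest.approx(125.0)
        assert scores.supply_ratio["h0"] == pytest.approx(0.08)
        assert scores.scores["bg0"] == pytest.approx(0.08)
        assert scores.scores["bg1"] == pytest.approx(0.08)

    def test_decay_free_limit_reduces_to_plain_ratio_sum(self):
        rng = np.random.default_rng(16)
        ds = random_dataset(rng)
        decay = make_decay(ds.supply.index, ["power"] * ds.n_supply,
                           np.ones(ds.n_supply), np.zeros(ds.n_supply))
        scores = revised_e2sfca(ds, decay, global_catchments(ds))
        P = ds.demand["population"].sum()
        expected = (ds.supply["capacity"] / P).sum()
        np.testing.assert_allclose(scores.scores.to_numpy(), expected, rtol=1e-9)

    @pytest.mark.parametrize("step2", ["ratio_sum", "weighted_sum"])
    def test_matches_brute_force_both_step2_modes(self, step2):
        rng = np.random.default_rng(17)
        ds = random_dataset(rng)
        forms = rng.choice(["power", "exponential"], ds.n_supply)
        decay = make_decay(ds.supply.index, forms,
                           rng.uniform(5, 80, ds.n_supply),
                           rng.uniform(-1.2, -0.1, ds.n_supply))
        catch = CatchmentSpec(
            supply_radii=pd.Series(rng.uniform(20, 90, ds.n_supply), index=ds.supply.index),
            demand_radii=pd.Series(rng.uniform(20, 90, ds.n_demand), index=ds.demand.index))
        scores = revised_e2sfca(ds, decay, catch, step2_weighting=step2)
        A, R = brute_force_revised(ds, decay, catch, step2)
        np.testing.assert_allclose(scores.scores.to_numpy(), A, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(scores.supply_ratio.to_numpy(), R, rtol=1e-9)

    def test_empty_catchments_yield_zero_not_infinity(self):
        ds = dataset_from_distances([[50.0], [70.0]], [100, 300], [10], [])
        decay = make_decay(ds.supply.index, ["power"], [1.0], [-1.0])
        catch = CatchmentSpec(supply_radii=pd.Series([5.0], index=ds.supply.index),
                              demand_radii=pd.Series([5.0, 5.0], index=ds.demand.index))
        scores = revised_e2sfca(ds, decay, catch)
        assert scores.supply_ratio["h0"] == 0.0
        assert (scores.scores == 0).all()

    def test_ratio_sum_does_not_conserve_supply(self):
        """Documented non-property: summing bare ratios over asymmetric
        catchments breaks the supply-conservation identity."""
        ds = dataset_from_distances([[2.0], [4.0]], [100, 300], [10], [])
        decay = make_decay(ds.supply.index, ["power"], [1.0], [-1.0])
        scores = revised_e2sfca(ds, decay, global_catchments(ds))
        lhs = float((ds.demand["population"] * scores.scores).sum())
        assert lhs != pytest.approx(float(ds.supply["capacity"].sum()), rel=1e-3)

    def test_monotone_in_supply_capacity(self):
        rng = np.random.default_rng(18)
        ds = random_dataset(rng)
        decay = make_decay(ds.supply.index, ["power"] * ds.n_supply,
                           np.full(ds.n_supply, 10.0), np.full(ds.n_supply, -0.8))
        catch = global_catchments(ds)
        base = revised_e2sfca(ds, decay, catch).scores
        bigger = ds.supply.copy()
        bigger.loc["h0", "capacity"] *= 3
        ds2 = type(ds)(demand=ds.demand, supply=bigger, flows=ds.flows,
                       distances=ds.distances)
        boosted = revised_e2sfca(ds2, decay, catch).scores
        assert (boosted >= base - 1e-12).all()

    def test_shrinking_radius_never_increases_weighted_demand(self):
        rng = np.random.default_rng(19)
        ds = random_dataset(rng)
        decay = make_decay(ds.supply.index, ["power"] * ds.n_supply,
                           np.full(ds.n_supply, 10.0), np.full(ds.n_supply, -0.8))
        wide = revised_e2sfca(ds, decay, global_catchments(ds, 100.0))
        narrow = revised_e2sfca(ds, decay, global_catchments(ds, 30.0))
        assert (narrow.weighted_demand <= wide.weighted_demand + 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(20)
        ds = random_dataset(rng)
        decay = make_decay(ds.supply.index, ["power"] * ds.n_supply,
                           np.full(ds.n_supply, 5.0), np.full(ds.n_supply, -0.5))
        catch = global_catchments(ds, 60.0)
        base = revised_e2sfca(ds, decay, catch).scores
        perm = rng.permutation(ds.n_demand)
        ds2 = type(ds)(demand=ds.demand.iloc[perm], supply=ds.supply, flows=ds.flows,
                       distances=type(ds.distances)(
                           values=ds.distances.values[perm], demand_ids=ds.demand.index[perm],
                           supply_ids=ds.supply.index))
        shuffled = revised_e2sfca(ds2, decay,
                                  CatchmentSpec(supply_radii=catch.supply_radii,
                                                demand_radii=catch.demand_radii.iloc[perm])
                                  ).scores
        np.testing.assert_allclose(shuffled.loc[base.index].to_numpy(),
                                   base.to_numpy(), rtol=1e-12)


class TestResolvers:
    def test_catchments_pass_through_vwad(self, toy_dataset):
        spec = resolve_catchments(toy_dataset, min_radius=0.01)
        diag = interaction_summary(toy_dataset)
        assert spec.supply_radii["h0"] == pytest.approx(diag.per_hospital.loc["h0", "vwad"])

    def test_zero_flow_entity_gets_median_fallback(self, toy_dataset):
        spec = resolve_catchments(toy_dataset, min_radius=0.01)
        diag = interaction_summary(toy_dataset)
        # bg2 has no flows -> median of the two fitted block-group VWADs
        expected = float(diag.per_demand["vwad"].median(skipna=True))
        assert spec.demand_radii["bg2"] == pytest.approx(expected)

    def test_min_radius_floor(self, toy_dataset):
        spec = resolve_catchments(toy_dataset, min_radius=5.0)
        assert (spec.supply_radii >= 5.0).all()
        assert (spec.demand_radii >= 5.0).all()

    def test_no_flows_at_all_is_configuration_error(self):
        ds = dataset_from_distances(np.ones((2, 2)), [1, 1], [1, 1], [])
        with pytest.raises(ConfigurationError):
            resolve_catchments(ds)

    def test_decay_fallback_uses_median_power_parameters(self):
        ds = dataset_from_distances(
            [[1.0, 2.0, 3.0], [5.0, 3.0, 4.0], [9.0, 4.0, 8.0], [12.0, 6.0, 2.0]],
            [1, 1, 1, 1], [1, 1, 1],
            [("bg0", "h0", 40), ("bg1", "h0", 12), ("bg2", "h0", 6), ("bg3", "h0", 4),
             ("bg0", "h1", 30), ("bg1", "h1", 20), ("bg2", "h1", 15), ("bg3", "h1", 10)])
        cals, _ = calibrate_hospitals(ds)
        params = resolve_decay_parameters(cals, ds.supply.index)
        assert not params.table.loc["h0", "fallback"]
        assert params.table.loc["h2", "fallback"]  # no flows at all
        fitted_betas = [cals["h0"].power.beta, cals["h1"].power.beta]
        assert params.table.loc["h2", "beta"] == pytest.approx(np.median(fitted_betas))

    def test_force_power_law_uses_power_fit_everywhere(self):
        rng = np.random.default_rng(21)
        ds = random_dataset(rng)
        cals, _ = calibrate_hospitals(ds)
        params = resolve_decay_parameters(cals, ds.supply.index, force_power_law=True)
        assert (params.table["form"] == "power").all()


class TestMinMaxNormalize:
    def test_affine_identity(self):
        np.testing.assert_allclose(minmax_normalize([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_constant_vector_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(22)
        x = rng.uniform(0, 10, 50)
        once = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_normalize([])
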