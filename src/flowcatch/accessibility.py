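"""Two-step floating catchment area accessibility scores.

Two variants are provided:

* :func:`traditional_e2sfca` — the classic enhanced 2SFCA with nested
  travel zones and stepwise weights, identical for every facility;
* :func:`revised_e2sfca` — the mobility-driven revision: each entity's
  catchment radius is its visit-weighted average distance (VWAD) and each
  hospital carries its own calibrated decay kernel.

Both produce a supply-to-demand ratio R_j per hospital (step 1) and an
accessibility score A_i per block group (step 2), plus a min-max
normalized variant for comparability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flowcatch.core_data import StudyDataset
from flowcatch.diagnostics import interaction_summary
from flowcatch.errors import ConfigurationError, DegenerateInputError
from flowcatch.decay import HospitalCalibration

logger = logging.getLogger(__name__)

__all__ = [
    "TraditionalConfig",
    "DecayParameterSet",
    "CatchmentSpec",
    "AccessibilityScores",
    "traditional_e2sfca",
    "revised_e2sfca",
    "resolve_catchments",
    "resolve_decay_parameters",
    "minmax_normalize",
]


@dataclass(frozen=True)
class TraditionalConfig:
    """Nested travel zones for the stepwise E2SFCA.

    Defaults are the canonical three 10-mile rings with Gaussian-derived
    weights used throughout the E2SFCA literature.
    """

    breakpoints: tuple = (10.0, 20.0, 30.0)
    weights: tuple = (1.0, 0.68, 0.22)

    def __post_init__(self):
        bp, wt = self.breakpoints, self.weights
        if len(bp) != len(wt) or not bp:
            raise ConfigurationError("breakpoints and weights must align and be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if any(not (0 < w <= 1) for w in wt) or any(w2 > w1 for w1, w2 in zip(wt, wt[1:])):
            raise ConfigurationError("weights must lie in (0, 1] and be non-increasing")

    def zone_weights(self, distances: np.ndarray) -> np.ndarray:
        """Stepwise weight for each distance; zero beyond the outermost ring."""
        bp = np.asarray(self.breakpoints)
        wt = np.concatenate([np.asarray(self.weights), [0.0]])
        zone = np.searchsorted(bp, distances, side="left")
        return wt[zone]


@dataclass(frozen=True)
class DecayParameterSet:
    """Resolved decay kernel per hospital: form, alpha, beta (beta < 0 = decay).

    ``table`` is indexed by hospital id with columns form / alpha / beta /
    fallback (True where parameters were imputed).
    """

    table: pd.DataFrame

    def weights(self, distances: np.ndarray, supply_ids: pd.Index) -> np.ndarray:
        """Kernel weight matrix w[i, j] = f_j(d[i, j]) for all hospitals."""
        tab = self.table.loc[supply_ids]
        alpha = tab["alpha"].to_numpy()[None, :]
        beta = tab["beta"].to_numpy()[None, :]
        is_power = (tab["form"] == "power").to_numpy()[None, :]
        return np.where(is_power,
                        alpha * distances ** beta,
                        alpha * np.exp(beta * distances))


@dataclass(frozen=True)
class CatchmentSpec:
    """Per-entity catchment radii in miles (VWAD-derived, with fallbacks)."""

    supply_radii: pd.Series
    demand_radii: pd.Series


@dataclass
class AccessibilityScores:
    """Raw and min-max normalized accessibility per demand site, plus the
    per-hospital supply ratios and weighted-demand denominators behind them."""

    scores: pd.Series
    normalized: pd.Series
    supply_ratio: pd.Series
    weighted_demand: pd.Series = field(default=None)


def minmax_normalize(values) -> np.ndarray:
    """Rescale to [0, 1]; a constant vector maps to zeros (with a warning)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant scores: min-max normalization returns zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _package(dataset: StudyDataset, a: np.ndarray, r: np.ndarray,
             wd: np.ndarray | None = None) -> AccessibilityScores:
    scores = pd.Series(a, index=dataset.demand.index, name="raw_score")
    return AccessibilityScores(
        scores=scores,
        normalized=pd.Series(minmax_normalize(a), index=dataset.demand.index,
                             name="normalized_score") if np.ptp(a) > 0
        else pd.Series(np.zeros_like(a), index=dataset.demand.index, name="normalized_score"),
        supply_ratio=pd.Series(r, index=dataset.supply.index, name="supply_ratio"),
        weighted_demand=None if wd is None
        else pd.Series(wd, index=dataset.supply.index, name="weighted_demand"))


def traditional_e2sfca(dataset: StudyDataset,
                       config: TraditionalConfig | None = None) -> AccessibilityScores:
    """Classic stepwise E2SFCA.

    Step 1: R_j = S_j / sum_i W(zone(d_ij)) * P_i over sites inside the
    outermost ring. Step 2: A_i = sum_j W(zone(d_ij)) * R_j. Hospitals with
    zero weighted demand get R_j = 0 (an unserved facility contributes no
    accessibility rather than infinite accessibility).
    """
    config = config or TraditionalConfig()
    W = config.zone_weights(dataset.distances.values)
    P = dataset.demand["population"].to_numpy(dtype=float)
    S = dataset.supply["capacity"].to_numpy(dtype=float)

    demand_j = W.T @ P
    zero = demand_j <= 0
    if zero.any():
        logger.warning("%d hospital(s) have zero weighted demand; R_j set to 0", zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(zero, 0.0, S / np.where(zero, 1.0, demand_j))
    A = W @ R
    return _package(dataset, A, R, demand_j)


def revised_e2sfca(dataset: StudyDataset, decay: DecayParameterSet,
                   catchments: CatchmentSpec, step2_weighting: str = "ratio_sum",
                   ) -> AccessibilityScores:
    """Mobility-driven E2SFCA with dynamic catchments and per-hospital decay.

    Step 1: C_j = {i : d_ij <= radius_j}; WeightedDemand_j =
    sum_{i in C_j} f_j(d_ij) * P_i; R_j = S_j / WeightedDemand_j.
    Step 2: C_i = {j : d_ij <= radius_i}; A_i = sum_{j in C_i} R_j under
    ``ratio_sum`` (the literal two-step accumulation) or
    sum f_j(d_ij) * R_j under ``weighted_sum`` (restores distance decay in
    the second step). Empty catchments yield R_j = 0 / A_i = 0.
    """
    if step2_weighting not in ("ratio_sum", "weighted_sum"):
        raise ConfigurationError(f"unknown step2_weighting {step2_weighting!r}")

    D = dataset.distances.values
    P = dataset.demand["population"].to_numpy(dtype=float)
    S = dataset.supply["capacity"].to_numpy(dtype=float)
    radius_j = catchments.supply_radii.loc[dataset.supply.index].to_numpy(dtype=float)
    radius_i = catchments.demand_radii.loc[dataset.demand.index].to_numpy(dtype=float)

    F = decay.weights(D, dataset.supply.index)

    in_cj = D <= radius_j[None, :]
    weighted_demand = ((F * in_cj) * P[:, None]).sum(axis=0)
    zero = weighted_demand <= 0
    if zero.any():
        logger.warning("%d hospital(s) have empty catchments; R_j set to 0", zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(zero, 0.0, S / np.where(zero, 1.0, weighted_demand))

    in_ci = D <= radius_i[:, None]
    if step2_weighting == "ratio_sum":
        A = (in_ci * R[None, :]).sum(axis=1)
    else:
        A = (in_ci * F * R[None, :]).sum(axis=1)
    return _package(dataset, A, R, weighted_demand)


def resolve_catchments(dataset: StudyDataset, fallback: str = "median",
                       fallback_radius: float | None = None,
                       min_radius: float = 0.1) -> CatchmentSpec:
    """Catchment radii from per-entity VWAD, with fallbacks for zero-flow entities.

    ``fallback='median'`` gives zero-flow entities the study-wide median
    VWAD of their own side; ``fallback='global'`` uses ``fallback_radius``.
    All radii are floored at ``min_radius`` miles.
    """
    if dataset.flows.empty:
        raise ConfigurationError("cannot resolve catchments: no flows at all")
    diag = interaction_summary(dataset)

    def _resolve(vwad: pd.Series) -> pd.Series:
        if fallback == "median":
            fill = float(vwad.median(skipna=True))
        elif fallback == "global":
            if fallback_radius is None:
                raise ConfigurationError("fallback='global' requires fallback_radius")
            fill = float(fallback_radius)
        else:
            raise ConfigurationError(f"unknown fallback {fallback!r}")
        n_missing = int(vwad.isna().sum())
        if n_missing:
            logger.warning("%d entities lack flows; using fallback radius %.2f mi",
                           n_missing, fill)
        return vwad.fillna(fill).clip(lower=min_radius)

    return CatchmentSpec(supply_radii=_resolve(diag.per_hospital["vwad"]),
                         demand_radii=_resolve(diag.per_demand["vwad"]))


def resolve_decay_parameters(calibrations: dict[str, HospitalCalibration],
                             supply_ids: pd.Index,
                             force_power_law: bool = True) -> DecayParameterSet:
    """Resolve a usable decay kernel for every hospital.

    With ``force_power_law`` (the default) every hospital uses its fitted
    power-law parameters regardless of classification, matching the revised
    model's single-form accumulation. Otherwise each hospital uses its
    classified form, and 'no clear decay' hospitals fall back like
    unfittable ones: the median power-law parameters across fitted
    hospitals (so no facility silently vanishes from the supply side).
    """
    rows = {}
    for hid in supply_ids:
        cal = calibrations.get(hid)
        if cal is None or not cal.fittable:
            rows[hid] = None
            continue
        if force_power_law:
            fit = cal.power
        else:
            fit = cal.classified if cal.classified.form != "none" else None
        rows[hid] = fit

    fitted = [f for f in rows.values() if f is not None]
    if not fitted:
        raise ConfigurationError("no hospital could be calibrated; no fallback available")
    power_pool = [f for f in fitted if f.form == "power"] or fitted
    med_alpha = float(np.median([f.alpha for f in power_pool]))
    med_beta = float(np.median([f.beta for f in power_pool]))

    records = []
    for hid in supply_ids:
        fit = rows[hid]
        if fit is None:
            records.append({"hospital_id": hid, "form": "power",
                            "alpha": med_alpha, "beta": med_beta, "fallback": True})
        else:
            records.append({"hospital_id": hid, "form": fit.form,
                            "alpha": fit.alpha, "beta": fit.beta, "fallback": False})
    table = pd.DataFrame(records).set_index("hospital_id")
    n_fb = int(table["fallback"].sum())
    if n_fb:
        logger.warning("%d hospital(s) received fallback decay parameters "
                       "(alpha=%.3g, beta=%.3g)", n_fb, med_alpha, med_beta)
    return DecayParameterSet(table=table)
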