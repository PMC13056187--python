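"""Empirical diagnostics of catchment-area assumptions.

Floating catchment models assume patient-provider interaction is bounded
and localized. These metrics quantify how localized observed flows really
are, from both perspectives:

* coverage / choice ratios — what fraction of all possible counterparts an
  entity actually interacts with (N_j / N_BG for hospitals, M_i / N_Hosp
  for block groups);
* visit-weighted average distance (VWAD) — mean interaction distance
  weighted by visit counts, later reused as a dynamic catchment radius;
* relative weighted distance (RWD) — VWAD divided by the unweighted mean
  distance to *all* counterparts; values well below 1 indicate localized,
  catchment-like behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from flowcatch.core_data import StudyDataset
from flowcatch.errors import DegenerateInputError

__all__ = [
    "DiagnosticsSummary",
    "visit_weighted_average_distance",
    "hospital_coverage_ratio",
    "hospital_relative_weighted_distance",
    "population_choice_ratio",
    "population_relative_weighted_distance",
    "interaction_summary",
]


@dataclass
class DiagnosticsSummary:
    """Per-entity interaction metrics plus their global aggregates.

    ``per_hospital`` columns: n_visitors, coverage_ratio, vwad,
    mean_distance_all, rwd, total_visits. ``per_demand`` columns:
    n_hospitals, choice_ratio, vwad, mean_distance_all, rwd, total_visits.
    ``summary`` holds the scalar aggregates (means and medians); entities
    with zero flows are excluded from visit-weighted averages but retained
    in counts and coverage denominators.
    """

    per_hospital: pd.DataFrame
    per_demand: pd.DataFrame
    summary: dict


def _vwad(weights: np.ndarray, distances: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("entity has no positive visits; VWAD undefined")
    return float((weights * distances).sum() / total)


def visit_weighted_average_distance(dataset: StudyDataset, entity_id: str,
                                    perspective: str) -> float:
    """VWAD for one hospital (``perspective='supply'``) or block group (``'demand'``).

    Sum of visits x distance over partners with positive visits, divided by
    total visits. Raises :class:`DegenerateInputError` when the entity has
    no flows.
    """
    w = dataset.flow_matrix()
    d = dataset.distances.values
    if perspective == "supply":
        j = dataset.supply.index.get_loc(entity_id)
        return _vwad(w[:, j], d[:, j])
    if perspective == "demand":
        i = dataset.demand.index.get_loc(entity_id)
        return _vwad(w[i, :], d[i, :])
    raise ValueError(f"perspective must be 'supply' or 'demand', got {perspective!r}")


def hospital_coverage_ratio(dataset: StudyDataset, hospital_id: str) -> float:
    """Fraction of all block groups with at least one visit to this hospital."""
    j = dataset.supply.index.get_loc(hospital_id)
    n_j = int((dataset.flow_matrix()[:, j] > 0).sum())
    return n_j / dataset.n_demand


def population_choice_ratio(dataset: StudyDataset, demand_id: str) -> float:
    """Fraction of all hospitals this block group actually visits."""
    i = dataset.demand.index.get_loc(demand_id)
    m_i = int((dataset.flow_matrix()[i, :] > 0).sum())
    return m_i / dataset.n_supply


def hospital_relative_weighted_distance(dataset: StudyDataset, hospital_id: str) -> float:
    """VWAD_j divided by the hospital's unweighted mean distance to all block groups."""
    j = dataset.supply.index.get_loc(hospital_id)
    vwad = visit_weighted_average_distance(dataset, hospital_id, "supply")
    return vwad / float(dataset.distances.values[:, j].mean())


def population_relative_weighted_distance(dataset: StudyDataset, demand_id: str) -> float:
    """VWAD_i divided by the block group's unweighted mean distance to all hospitals."""
    i = dataset.demand.index.get_loc(demand_id)
    vwad = visit_weighted_average_distance(dataset, demand_id, "demand")
    return vwad / float(dataset.distances.values[i, :].mean())


def interaction_summary(dataset: StudyDataset) -> DiagnosticsSummary:
    """All per-entity interaction metrics plus global means/medians.

    Vectorized over the dense flow and distance matrices. Zero-flow
    entities carry NaN in vwad/rwd, are excluded from the visit-weighted
    aggregates, and are counted in totals and count averages.
    """
    if dataset.flows.empty:
        raise DegenerateInputError("flow table is empty; no interactions to summarize")

    w = dataset.flow_matrix()
    d = dataset.distances.values

    with np.errstate(invalid="ignore", divide="ignore"):
        tot_j = w.sum(axis=0)
        vwad_j = np.where(tot_j > 0, (w * d).sum(axis=0) / np.where(tot_j > 0, tot_j, 1.0), np.nan)
        tot_i = w.sum(axis=1)
        vwad_i = np.where(tot_i > 0, (w * d).sum(axis=1) / np.where(tot_i > 0, tot_i, 1.0), np.nan)

    mean_d_j = d.mean(axis=0)  # hospital j to all block groups
    mean_d_i = d.mean(axis=1)  # block group i to all hospitals

    per_hospital = pd.DataFrame({
        "n_visitors": (w > 0).sum(axis=0),
        "coverage_ratio": (w > 0).sum(axis=0) / dataset.n_demand,
        "vwad": vwad_j,
        "mean_distance_all": mean_d_j,
        "rwd": vwad_j / mean_d_j,
        "total_visits": tot_j,
    }, index=dataset.supply.index)

    per_demand = pd.DataFrame({
        "n_hospitals": (w > 0).sum(axis=1),
        "choice_ratio": (w > 0).sum(axis=1) / dataset.n_supply,
        "vwad": vwad_i,
        "mean_distance_all": mean_d_i,
        "rwd": vwad_i / mean_d_i,
        "total_visits": tot_i,
    }, index=dataset.demand.index)

    summary = {
        "n_block_groups": dataset.n_demand,
        "n_hospitals": dataset.n_supply,
        "total_visits": float(w.sum()),
        "mean_vwad_hospital": float(np.nanmean(vwad_j)),
        "median_vwad_hospital": float(np.nanmedian(vwad_j)),
        "mean_vwad_blockgroup": float(np.nanmean(vwad_i)),
        "median_vwad_blockgroup": float(np.nanmedian(vwad_i)),
        "mean_distance_hospital_to_all": float(mean_d_j.mean()),
        "mean_distance_blockgroup_to_all": float(mean_d_i.mean()),
        "mean_hosrwd": float(np.nanmean(per_hospital["rwd"])),
        "median_hosrwd": float(np.nanmedian(per_hospital["rwd"])),
        "mean_poprwd": float(np.nanmean(per_demand["rwd"])),
        "median_poprwd": float(np.nanmedian(per_demand["rwd"])),
        "avg_blockgroups_per_hospital": float(per_hospital["n_visitors"].mean()),
        "avg_hospitals_per_blockgroup": float(per_demand["n_hospitals"].mean()),
    }
    return DiagnosticsSummary(per_hospital=per_hospital, per_demand=per_demand, summary=summary)
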