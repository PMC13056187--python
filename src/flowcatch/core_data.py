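"""Domain containers, CSV/GeoJSON I/O, and geodesic distances.

Sites live in pandas DataFrames indexed by their id. Demand sites (census
block groups) carry a ``population`` column and optionally ``income`` and
``region_id``; supply sites (hospitals) carry a ``capacity`` column
(licensed beds). Flows are a sparse long-format DataFrame with columns
``demand_id``, ``supply_id``, ``visits``; an absent pair means zero visits.
All distances are statute miles between site centroids.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flowcatch.errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Mean Earth radius in statute miles, the sphere used for geodesic distances.
EARTH_RADIUS_MILES = 3958.8

#: Default floor applied to pairwise distances (miles). Power-law decay
#: weights d**beta diverge as d -> 0, so coincident centroids are clamped.
DEFAULT_DISTANCE_FLOOR = 0.1

_ROLE_VALUE_COLUMN = {"demand": "population", "supply": "capacity"}


def geodesic_distance(lat1, lon1, lat2, lon2):
    """Great-circle (haversine) distance in statute miles.

    Accepts scalars or broadcastable arrays of WGS84 decimal degrees.
    Computed on the mean-radius sphere; the difference from an ellipsoidal
    geodesic is below 0.5% at the scales catchment models operate on.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValidationError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValidationError("longitude outside [-180, 180]")
    if np.any(np.isnan(lat1)) or np.any(np.isnan(lat2)) or np.any(np.isnan(lon1)) or np.any(np.isnan(lon2)):
        raise ValidationError("coordinates contain NaN")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_MILES * 2.0 * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class DistanceMatrix:
    """Dense demand x supply matrix of pairwise geodesic distances (miles).

    ``values[i, j]`` is the (floored) distance between ``demand_ids[i]`` and
    ``supply_ids[j]``. Recomputation from coordinates is deterministic.
    """

    values: np.ndarray
    demand_ids: pd.Index
    supply_ids: pd.Index
    floor: float = DEFAULT_DISTANCE_FLOOR

    def lookup(self, demand_id: str, supply_id: str) -> float:
        i = self.demand_ids.get_loc(demand_id)
        j = self.supply_ids.get_loc(supply_id)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.demand_ids, columns=self.supply_ids)


def build_distance_matrix(demand: pd.DataFrame, supply: pd.DataFrame,
                          floor: float = DEFAULT_DISTANCE_FLOOR) -> DistanceMatrix:
    """All pairwise demand-supply geodesic distances, floored at ``floor`` miles."""
    if floor <= 0:
        raise ConfigurationError("distance floor must be positive")
    d = geodesic_distance(
        demand["lat"].to_numpy()[:, None], demand["lon"].to_numpy()[:, None],
        supply["lat"].to_numpy()[None, :], supply["lon"].to_numpy()[None, :],
    )
    d = np.maximum(d, floor)
    return DistanceMatrix(values=d, demand_ids=demand.index, supply_ids=supply.index, floor=floor)


def validate_sites(df: pd.DataFrame, role: str) -> pd.DataFrame:
    """Validate a raw site table; drop rows with missing/out-of-range coordinates.

    Dropped ids are recorded in ``result.attrs["rejected_ids"]`` and logged.
    Duplicate ids and negative population / non-positive capacity raise
    :class:`ValidationError`.
    """
    if role not in _ROLE_VALUE_COLUMN:
        raise ConfigurationError(f"unknown site role {role!r}")
    value_col = _ROLE_VALUE_COLUMN[role]
    required = ["id", "lat", "lon", value_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")

    df = df.copy()
    df["id"] = df["id"].astype(str)
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate {role} site id(s): {dupes}")

    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    rejected = df.loc[bad, "id"].tolist()
    if rejected:
        logger.warning("dropping %d %s site(s) with invalid coordinates: %s",
                       len(rejected), role, rejected)
    df = df.loc[~bad].copy()
    df["lat"], df["lon"] = lat[~bad], lon[~bad]
    df[value_col] = pd.to_numeric(df[value_col], errors="coerce")

    if role == "demand":
        if (df["population"] < 0).any():
            raise ValidationError("negative population")
        df["population"] = df["population"].fillna(0.0)
    else:
        if (df["capacity"] <= 0).any() or df["capacity"].isna().any():
            raise ValidationError("capacity must be positive")

    df = df.set_index("id")
    df.attrs["rejected_ids"] = rejected
    return df


def load_sites(path, role: str, column_map: dict | None = None) -> pd.DataFrame:
    """Load and validate a demand or supply site CSV.

    ``column_map`` maps canonical names (``id``, ``lat``, ``lon``,
    ``population``/``capacity``, ``income``, ``region_id``) to the column
    names actually present in the file.
    """
    raw = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        missing = [src for src in column_map.values() if src not in raw.columns]
        if missing:
            raise ConfigurationError(f"mapped column(s) not found in {path}: {missing}")
        raw = raw.rename(columns=rename)
    return validate_sites(raw, role)


def load_flows(path, demand: pd.DataFrame, supply: pd.DataFrame) -> pd.DataFrame:
    """Load an origin-destination visit-count CSV into a sparse flow table.

    Duplicate (demand_id, supply_id) pairs are summed (monthly panels are
    commonly split across rows), zero-visit rows are dropped, and rows whose
    ids do not resolve against the site tables are rejected and reported in
    ``result.attrs["rejected"]``.
    """
    raw = pd.read_csv(path)
    required = ["demand_id", "supply_id", "visits"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"flow file missing column(s): {missing}")
    return make_flow_table(raw, demand, supply)


def make_flow_table(raw: pd.DataFrame, demand: pd.DataFrame, supply: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize an in-memory flow frame (see :func:`load_flows`)."""
    flows = raw[["demand_id", "supply_id", "visits"]].copy()
    flows["demand_id"] = flows["demand_id"].astype(str)
    flows["supply_id"] = flows["supply_id"].astype(str)
    flows["visits"] = pd.to_numeric(flows["visits"])
    if (flows["visits"] < 0).any():
        raise ValidationError("negative visit counts")

    unresolved = ~flows["demand_id"].isin(demand.index) | ~flows["supply_id"].isin(supply.index)
    rejected = flows.loc[unresolved]
    if len(rejected):
        logger.warning("rejecting %d flow row(s) with unresolved ids", len(rejected))
    flows = flows.loc[~unresolved]

    flows = (flows.groupby(["demand_id", "supply_id"], as_index=False, sort=True)["visits"].sum())
    flows = flows.loc[flows["visits"] > 0].reset_index(drop=True)
    if flows.empty:
        warnings.warn("flow table is empty", stacklevel=2)
    flows.attrs["rejected"] = rejected.reset_index(drop=True)
    return flows


@dataclass
class StudyDataset:
    """Demand sites, supply sites, observed flows, and pairwise distances."""

    demand: pd.DataFrame
    supply: pd.DataFrame
    flows: pd.DataFrame
    distances: DistanceMatrix = field(repr=False)

    @classmethod
    def from_frames(cls, demand: pd.DataFrame, supply: pd.DataFrame, flows: pd.DataFrame,
                    floor: float = DEFAULT_DISTANCE_FLOOR) -> "StudyDataset":
        bad_d = set(flows["demand_id"]) - set(demand.index)
        bad_s = set(flows["supply_id"]) - set(supply.index)
        if bad_d or bad_s:
            raise ValidationError(f"flow ids do not resolve: {sorted(bad_d | bad_s)[:5]}")
        return cls(demand=demand, supply=supply, flows=flows,
                   distances=build_distance_matrix(demand, supply, floor=floor))

    @property
    def n_demand(self) -> int:
        return len(self.demand)

    @property
    def n_supply(self) -> int:
        return len(self.supply)

    def flow_matrix(self) -> np.ndarray:
        """Dense demand x supply visit-count matrix aligned with the distance matrix."""
        w = np.zeros((self.n_demand, self.n_supply))
        i = self.demand.index.get_indexer(self.flows["demand_id"])
        j = self.supply.index.get_indexer(self.flows["supply_id"])
        w[i, j] = self.flows["visits"].to_numpy(dtype=float)
        return w


def write_scores(scores, path, fmt: str = "csv", demand: pd.DataFrame | None = None) -> None:
    """Write per-demand-site accessibility scores to CSV or GeoJSON.

    ``scores`` may be an :class:`~flowcatch.accessibility.AccessibilityScores`
    or anything with ``scores``/``normalized`` Series attributes. GeoJSON
    output (RFC 7946 FeatureCollection of Points) requires ``demand`` for
    the coordinates.
    """
    table = pd.DataFrame({
        "id": scores.scores.index,
        "raw_score": scores.scores.to_numpy(),
        "normalized_score": scores.normalized.to_numpy(),
    })
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "geojson":
        if demand is None:
            raise ConfigurationError("GeoJSON output requires the demand site table")
        features = []
        for _, row in table.iterrows():
            site = demand.loc[row["id"]]
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(site["lon"]), float(site["lat"])]},
                "properties": {"id": row["id"],
                               "raw_score": float(row["raw_score"]),
                               "normalized_score": float(row["normalized_score"])},
            })
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ConfigurationError(f"unknown output format {fmt!r}")


def read_scores(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_scores`."""
    return pd.read_csv(path, dtype={"id": str}).set_index("id")
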