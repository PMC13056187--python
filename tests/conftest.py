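import numpy as np
import pandas as pd
import pytest

from flowcatch.core_data import DistanceMatrix, StudyDataset


def dataset_from_distances(distances, populations, capacities, flow_records,
                           income=None, region=None):
    """Build a StudyDataset with an explicitly specified distance matrix.

    Coordinates are placed at dummy positions; the distance matrix is
    injected directly so hand-computed expectations stay exact.
    """
    distances = np.asarray(distances, dtype=float)
    n_d, n_s = distances.shape
    demand = pd.DataFrame({
        "lat": np.linspace(40.0, 41.0, n_d),
        "lon": np.linspace(-78.0, -77.0, n_d),
        "population": np.asarray(populations, dtype=float),
    }, index=pd.Index([f"bg{k}" for k in range(n_d)], name="id"))
    if income is not None:
        demand["income"] = income
    if region is not None:
        demand["region_id"] = region
    supply = pd.DataFrame({
        "lat": np.linspace(40.2, 40.8, n_s),
        "lon": np.linspace(-77.8, -77.2, n_s),
        "capacity": np.asarray(capacities, dtype=float),
    }, index=pd.Index([f"h{k}" for k in range(n_s)], name="id"))
    flows = pd.DataFrame(flow_records, columns=["demand_id", "supply_id", "visits"])
    dm = DistanceMatrix(values=distances, demand_ids=demand.index,
                        supply_ids=supply.index)
    return StudyDataset(demand=demand, supply=supply, flows=flows, distances=dm)


@pytest.fixture
def toy_dataset():
    """3 block groups x 2 hospitals with hand-checkable distances and flows.

    h0 sees bg0 (d=1, w=4) and bg1 (d=5, w=1); bg2 never visits (d=9).
    h1 sees bg1 only (d=2, w=3) and bg0 at d=10 with w=1.
    """
    distances = [[1.0, 10.0],
                 [5.0, 2.0],
                 [9.0, 7.0]]
    flows = [("bg0", "h0", 4), ("bg1", "h0", 1),
             ("bg1", "h1", 3), ("bg0", "h1", 1)]
    return dataset_from_distances(distances, [100, 300, 50], [10, 20], flows)


def random_dataset(rng, n_demand=30, n_supply=8):
    """Random geometric dataset with gravity-ish Poisson flows."""
    demand = pd.DataFrame({
        "lat": rng.uniform(40.0, 41.5, n_demand),
        "lon": rng.uniform(-78.5, -76.5, n_demand),
        "population": rng.integers(50, 5000, n_demand).astype(float),
    }, index=pd.Index([f"bg{k}" for k in range(n_demand)], name="id"))
    supply = pd.DataFrame({
        "lat": rng.uniform(40.0, 41.5, n_supply),
        "lon": rng.uniform(-78.5, -76.5, n_supply),
        "capacity": rng.integers(20, 800, n_supply).astype(float),
    }, index=pd.Index([f"h{k}" for k in range(n_supply)], name="id"))
    ds = StudyDataset.from_frames(demand, supply,
                                  pd.DataFrame(columns=["demand_id", "supply_id", "visits"]))
    lam = 40.0 * ds.distances.values ** -1.2
    w = rng.poisson(lam)
    i, j = np.nonzero(w)
    flows = pd.DataFrame({"demand_id": demand.index[i], "supply_id": supply.index[j],
                          "visits": w[i, j].astype(float)})
    return StudyDataset(demand=demand, supply=supply, flows=flows, distances=ds.distances)
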