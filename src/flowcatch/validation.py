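"""Validation statistics for comparing accessibility surfaces.

Covers the comparison toolkit: region-level aggregation of block-group
scores, Pearson correlation with external covariates, multivariate OLS,
the Gini index of score inequality, and Global Moran's I of spatial
clustering with permutation inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from flowcatch.errors import ConfigurationError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MoranResult",
    "OLSResult",
    "ValidationReport",
    "aggregate_to_region",
    "pearson_correlation",
    "ols_fit",
    "gini_index",
    "morans_i",
    "validation_report",
]


@dataclass(frozen=True)
class OLSResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    nobs: int


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    p_perm: float
    permutations: int


@dataclass
class ValidationReport:
    """Side-by-side comparison of two accessibility models."""

    pearson: dict  # covariate -> {model: (r, p)}
    gini: dict  # model -> Gini index
    moran: dict  # model -> MoranResult
    ols: dict | None = None  # model -> OLSResult

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for model in self.gini:
            rows[model] = {"gini": self.gini[model],
                           "morans_i": self.moran[model].I,
                           "morans_p": self.moran[model].p_perm}
            for cov, per_model in self.pearson.items():
                r, p = per_model[model]
                rows[model][f"r_{cov}"] = r
                rows[model][f"p_{cov}"] = p
        return pd.DataFrame(rows)


def aggregate_to_region(scores: pd.Series, demand: pd.DataFrame,
                        weighting: str = "population") -> pd.Series:
    """Aggregate block-group scores to regions (counties).

    Population-weighted mean by default; sites without a region_id are
    excluded with a warning.
    """
    if weighting not in ("population", "unweighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if "region_id" not in demand.columns:
        raise ConfigurationError("demand sites carry no region_id column")
    df = pd.DataFrame({"score": scores, "region": demand["region_id"],
                       "pop": demand["population"]})
    missing = df["region"].isna()
    if missing.any():
        logger.warning("excluding %d site(s) without region_id", int(missing.sum()))
        df = df.loc[~missing]
    if weighting == "unweighted":
        return df.groupby("region")["score"].mean()
    grouped = df.groupby("region")
    return grouped.apply(lambda g: np.average(g["score"], weights=g["pop"])
                         if g["pop"].sum() > 0 else g["score"].mean(),
                         include_groups=False)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(response, covariates: pd.DataFrame | dict) -> OLSResult:
    """Multivariate OLS with intercept; coefficients, SEs, p-values, R-squared."""
    X = pd.DataFrame(covariates)
    y = np.asarray(response, dtype=float)
    if len(X) != y.size or y.size <= X.shape[1] + 1:
        raise ValidationError("need more observations than parameters")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    return OLSResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                     r2=float(res.rsquared), nobs=int(res.nobs))


def gini_index(values) -> float:
    """Population Gini index of non-negative values.

    Mean absolute pairwise difference divided by twice the mean, computed
    via the sorted-rank identity: G = (2*sum(i*x_(i)))/(n*sum(x)) - (n+1)/n.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("Gini undefined on empty input")
    if np.any(x < 0):
        raise ValidationError("Gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise DegenerateInputError("Gini undefined when all values are zero")
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * xs).sum() / (n * total) - (n + 1) / n)


def _knn_weights(coords: np.ndarray, k: int) -> csr_matrix:
    n = coords.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} requires more than k sites (got {n})")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    data = np.full(n * k, 1.0 / k)  # row-standardized
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def _distance_band_weights(coords: np.ndarray, radius: float) -> csr_matrix:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        raise ConfigurationError("distance band produced no neighbors")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    W = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(coords.shape[0],) * 2)
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return csr_matrix(np.diag(inv)) @ W


def morans_i(values, coordinates, weights: str = "knn", k: int = 8,
             band_radius: float | None = None, permutations: int = 999,
             seed: int | None = None) -> MoranResult:
    """Global Moran's I with row-standardized spatial weights.

    ``weights='knn'`` builds k-nearest-neighbor weights on the (lat, lon)
    coordinates (planar metric — adequate at block-group spacing);
    ``'distance_band'`` connects all pairs within ``band_radius``. The
    pseudo p-value counts permuted |I*| at least as extreme as |I| under
    random relabeling: p = (1 + n_extreme) / (1 + permutations).
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError("Moran's I needs at least 4 sites")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Moran's I undefined for constant values")

    if weights == "knn":
        W = _knn_weights(coords, k)
    elif weights == "distance_band":
        if band_radius is None:
            raise ConfigurationError("distance_band weights require band_radius")
        W = _distance_band_weights(coords, band_radius)
    else:
        raise ConfigurationError(f"unknown weights scheme {weights!r}")

    s0 = W.sum()

    def _moran(z: np.ndarray) -> float:
        zc = z - z.mean()
        return float(n / s0 * (zc @ (W @ zc)) / (zc @ zc))

    I = _moran(x)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(permutations):
        if abs(_moran(rng.permutation(x))) >= abs(I):
            extreme += 1
    return MoranResult(I=I, expected=-1.0 / (n - 1),
                       p_perm=(1 + extreme) / (1 + permutations),
                       permutations=permutations)


def validation_report(score_sets: dict, demand: pd.DataFrame,
                      covariates: pd.DataFrame | None = None,
                      knn_k: int = 8, permutations: int = 999,
                      seed: int | None = None) -> ValidationReport:
    """Compare accessibility models on inequality, clustering, and covariates.

    ``score_sets`` maps model name -> per-demand-site score Series (aligned
    with ``demand``). ``covariates`` (indexed like demand) are correlated
    against each model's scores.
    """
    coords = demand[["lat", "lon"]].to_numpy()
    gini = {}
    moran = {}
    pearson: dict = {}
    for name, scores in score_sets.items():
        s = scores.loc[demand.index].to_numpy(dtype=float)
        gini[name] = gini_index(s)
        moran[name] = morans_i(s, coords, k=knn_k, permutations=permutations, seed=seed)
        if covariates is not None:
            for cov in covariates.columns:
                mask = covariates[cov].notna().to_numpy()
                r, p = pearson_correlation(s[mask], covariates.loc[mask, cov])
                pearson.setdefault(cov, {})[name] = (r, p)
    return ValidationReport(pearson=pearson, gini=gini, moran=moran)
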