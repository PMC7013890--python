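"""Global Moran's I spatial-autocorrelation check.

Positive global Moran's I with a large z-score indicates that similar outcome
values cluster in space — the dependence screen that motivates spatially
aware stratified analysis in the first place.  Weights default to
row-standardised k-nearest-neighbour (k = 8) structures on great-circle
(haversine) distances, since point-level accident records carry no areal
adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .records import AccidentTable

__all__ = ["SpatialWeights", "MoranResult", "build_weights", "moran_i", "MoranI"]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix with a description of how it was built."""

    matrix: sparse.csr_matrix
    spec: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MoranResult:
    i_statistic: float
    expected_i: float
    variance_i: float
    z_score: float
    p_value: float
    weights_spec: str

    def to_dict(self) -> dict:
        return vars(self).copy()


def build_weights(coords, scheme: str = "knn", k: int = 8,
                  row_standardize: bool = True) -> SpatialWeights:
    """Spatial weights from lon/lat points.

    ``scheme="knn"`` links each point to its ``k`` nearest neighbours by
    great-circle distance (binary links before standardisation);
    ``scheme="inverse_distance"`` weights every pair by 1/distance.
    Row standardisation scales each row to sum to 1.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of (lon, lat)")
    n = len(coords)
    if n < 2 or len(np.unique(coords, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points")
    # haversine metric expects (lat, lon) in radians
    latlon = np.radians(coords[:, ::-1])
    if scheme == "knn":
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="haversine").fit(latlon)
        _, idx = nn.kneighbors(latlon)
        rows = np.repeat(np.arange(n), k_eff)
        cols = idx[:, 1:].ravel()          # drop self
        data = np.ones(n * k_eff)
        w = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        spec = f"knn(k={k_eff}, haversine)"
    elif scheme == "inverse_distance":
        lat = latlon[:, 0][:, None]
        lon = latlon[:, 1][:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        with np.errstate(divide="ignore"):
            wdense = 1.0 / d
        np.fill_diagonal(wdense, 0.0)
        wdense[~np.isfinite(wdense)] = 0.0   # coincident points carry no weight
        w = sparse.csr_matrix(wdense)
        spec = "inverse_distance(haversine, km)"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if row_standardize:
        rowsum = np.asarray(w.sum(axis=1)).ravel()
        rowsum[rowsum == 0] = 1.0
        w = sparse.diags(1.0 / rowsum) @ w
        spec += ", row-standardized"
    return SpatialWeights(matrix=sparse.csr_matrix(w), spec=spec)


def moran_i(values, weights: SpatialWeights,
            permutations: int = 0, seed: int | None = None) -> MoranResult:
    """Global Moran's I with inference under the randomization assumption.

    I = (n / S0) * (z' W z) / (z' z) for deviations z = y - ybar.  The
    expectation is -1/(n-1); the variance uses the standard randomization
    moments (S0, S1, S2 and the sample kurtosis term), and the two-sided
    p-value refers z to a standard normal.  With ``permutations > 0`` the
    p-value is replaced by a permutation p-value instead.
    """
    y = np.asarray(values, dtype=float)
    w = weights.matrix
    n = len(y)
    if w.shape != (n, n):
        raise ValueError("weights shape does not match values")
    z = y - y.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("values are constant; Moran's I is undefined")
    s0 = float(w.sum())
    num = float(z @ (w @ z))
    i_obs = (n / s0) * (num / denom)

    wt = w.T.tocsr()
    s1 = 0.5 * float(((w + wt).multiply(w + wt)).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(np.sum((row + col) ** 2))
    e_i = -1.0 / (n - 1)
    b2 = n * float(np.sum(z**4)) / denom**2
    var_i = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zsc = (i_obs - e_i) / np.sqrt(var_i)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(permutations):
            zp = z[rng.permutation(n)]
            ip = (n / s0) * float(zp @ (w @ zp)) / denom
            if abs(ip - e_i) >= abs(i_obs - e_i) - 1e-15:
                exceed += 1
        p = (1 + exceed) / (1 + permutations)
    else:
        p = float(2 * stats.norm.sf(abs(zsc)))
    return MoranResult(
        i_statistic=float(i_obs), expected_i=e_i, variance_i=float(var_i),
        z_score=float(zsc), p_value=p, weights_spec=weights.spec,
    )


def moran_from_table(table: AccidentTable, outcome: str, scheme: str = "knn",
                     k: int = 8, **kwargs) -> MoranResult:
    """Moran's I of one outcome column of an accident table."""
    w = build_weights(table.coords(), scheme=scheme, k=k)
    return moran_i(table.outcome(outcome), w, **kwargs)


class MoranI(BaseEstimator):
    """Estimator wrapper: fit(coords, values) computes global Moran's I.

    Attributes
    ----------
    i_ : float
        Observed Moran's I.
    expected_i_, variance_i_, z_, p_value_ : float
        Randomization-assumption moments and test results.
    """

    def __init__(self, scheme: str = "knn", k: int = 8,
                 row_standardize: bool = True, permutations: int = 0,
                 random_state: int | None = None):
        self.scheme = scheme
        self.k = k
        self.row_standardize = row_standardize
        self.permutations = permutations
        self.random_state = random_state

    def fit(self, X, y):
        w = build_weights(X, scheme=self.scheme, k=self.k,
                          row_standardize=self.row_standardize)
        self.result_ = moran_i(y, w, permutations=self.permutations,
                               seed=self.random_state)
        self.i_ = self.result_.i_statistic
        self.expected_i_ = self.result_.expected_i
        self.variance_i_ = self.result_.variance_i
        self.z_ = self.result_.z_score
        self.p_value_ = self.result_.p_value
        return self
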