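"""Global and local (Anselin) Moran's I with inverse-distance weights.

Global Moran's I measures overall spatial autocorrelation of a variable
observed at n locations:

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),   z = x - mean(x)

with expectation E[I] = -1/(n-1) under no autocorrelation and an analytic
variance under the randomization (permutation) assumption — the default of
the common GIS implementations.  The local decomposition

    I_i = (z_i / m2) * sum_j w_ij z_j,    m2 = sum_i z_i^2 / n

identifies clusters (high-high, low-low) and outliers (high-low, low-high)
via conditional permutation p-values: observation i is held fixed while the
remaining values are permuted among the other locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError


@dataclass
class SpatialWeights:
    """n x n non-negative weights with zero diagonal."""

    matrix: np.ndarray
    row_standardized: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        W = self.matrix
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise DomainError("weight matrix must be square")
        if (W < 0).any():
            raise DomainError("weights must be non-negative")
        if np.diag(W).any():
            raise DomainError("weight matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S0(self) -> float:
        return float(self.matrix.sum())


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float


@dataclass
class LocalMoranResult:
    """Per-location Local Moran statistics and cluster classification."""

    I: np.ndarray
    p: np.ndarray
    cluster: list[str]  # HH, LL, HL, LH or ns


def inverse_distance_weights(
    centroids: np.ndarray,
    row_standardize: bool = True,
    *,
    jitter_km: float = 0.0,
    seed: int | None = None,
) -> SpatialWeights:
    """w_ij = 1 / d_ij on pairwise Euclidean distances.

    Coincident centroids make 1/d blow up, so they raise, naming the
    offending pair; callers may instead pass ``jitter_km`` to displace every
    point uniformly within that radius first (seeded).
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise DomainError("need at least two centroids")
    if jitter_km > 0.0:
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        r = jitter_km * np.sqrt(rng.uniform(0, 1, n))
        pts = pts + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    iu = np.triu_indices(n, 1)
    zero = np.argwhere((d[iu] == 0.0))
    if zero.size:
        i, j = iu[0][zero[0, 0]], iu[1][zero[0, 0]]
        raise DomainError(
            f"coincident centroids at indices {i} and {j}; pass jitter_km to displace"
        )
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return SpatialWeights(matrix=W, row_standardized=row_standardize)


def _check_values(values: np.ndarray, W: SpatialWeights) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if len(x) != W.n:
        raise DomainError(f"{len(x)} values for {W.n} locations")
    if W.n < 3:
        raise DomainError("need at least three locations")
    if np.ptp(x) == 0.0:
        raise DomainError("values are constant; Moran's I undefined")
    return x


def global_morans_i(values: np.ndarray, W: SpatialWeights) -> MoranResult:
    """Global Moran's I with the randomization-assumption analytic variance."""
    x = _check_values(values, W)
    n = W.n
    z = x - x.mean()
    S0 = W.S0
    num = float(z @ W.matrix @ z)
    I = (n / S0) * num / float(z @ z)

    Wm = W.matrix
    S1 = 0.5 * float(((Wm + Wm.T) ** 2).sum())
    S2 = float(((Wm.sum(axis=1) + Wm.sum(axis=0)) ** 2).sum())
    EI = -1.0 / (n - 1)
    b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
    var = (
        n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
        - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * S0**2) - EI**2
    zscore = (I - EI) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=EI, variance=float(var), z=float(zscore), p=float(p))


def local_morans_i(
    values: np.ndarray,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LocalMoranResult:
    """Anselin Local Moran's I with conditional permutation inference.

    For each location i the observed value stays put while the other n-1
    values are permuted over the other locations; the two-sided p-value uses
    the usual (count + 1)/(n_perm + 1) estimator.  Locations significant at
    ``alpha`` are classed HH/LL (clusters) or HL/LH (outliers) from the sign
    of their deviate and of the spatial lag of the permuted-over neighbours;
    the rest are "ns".
    """
    x = _check_values(values, W)
    if n_perm < 99:
        raise DomainError("n_perm must be at least 99")
    n = W.n
    z = x - x.mean()
    m2 = float(z @ z) / n
    lag = W.matrix @ z
    I_obs = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(W.matrix[i], i)
        # permute neighbours' values; I_i sign/magnitude depends only on the lag
        perms = np.empty(n_perm)
        for k in range(n_perm):
            perms[k] = z[i] * (wi @ rng.permutation(others)) / m2
        ge = int((perms >= I_obs[i]).sum())
        le = int((perms <= I_obs[i]).sum())
        p[i] = min(1.0, 2.0 * (min(ge, le) + 1) / (n_perm + 1))

    cluster = []
    for i in range(n):
        if p[i] >= alpha:
            cluster.append("ns")
        elif z[i] > 0:
            cluster.append("HH" if lag[i] > 0 else "HL")
        else:
            cluster.append("LL" if lag[i] < 0 else "LH")
    return LocalMoranResult(I=I_obs, p=p, cluster=cluster)


def moran_frame(
    species_ids: list[str], local: LocalMoranResult
) -> pd.DataFrame:
    """Tidy per-location table of local Moran output."""
    return pd.DataFrame(
        {
            "species_id": species_ids,
            "local_I": local.I,
            "p": local.p,
            "cluster": local.cluster,
        }
    )
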