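"""Landscapes: local sites with controlled environment-space covariance.

A landscape is a set of local sites, each with ``D_S`` spatial coordinates
and ``D_E`` environmental variables, all standardized to z-scores. The
degree of environmental spatial structure is summarized by sigma_ES, the
covariance between environmental axis *i* and spatial axis *j* across
sites. Because all columns are z-scores, sigma_ES is the Pearson
correlation and lies in [0, 1) here.

The generator constructs sites so that the *realized* sample covariance
equals the requested target exactly: cov(E_i, S_i) = target and
cov(E_i, S_j) = 0 for i != j. Exact construction (rather than drawing
from a multivariate normal and accepting Monte-Carlo slop) matters
because every downstream variance-partitioning expectation is
conditioned on the environment-space correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError

__all__ = ["Landscape", "generate_landscape", "read_sites_csv", "write_sites_csv"]

# All moments use the population convention (ddof=0); with z-scored
# columns the covariance equals the Pearson correlation either way.
_STD_DDOF = 0


@dataclass(frozen=True)
class Landscape:
    """Local sites with z-scored coordinates and environments.

    Attributes
    ----------
    site_ids : list of str
        One identifier per site.
    S : ndarray, shape (n_sites, D_S)
        Spatial coordinates, each column mean 0 / sd 1.
    E : ndarray, shape (n_sites, D_E)
        Environmental values, each column mean 0 / sd 1.
    sigma_ES : ndarray, shape (D_E, D_S)
        Realized sample covariance between each environmental axis and
        each spatial axis.
    """

    site_ids: list[str]
    S: np.ndarray
    E: np.ndarray
    sigma_ES: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if S.ndim != 2 or E.ndim != 2 or S.shape[0] != E.shape[0]:
            raise InvalidArgumentError("S and E must be 2-D with equal site counts")
        if S.shape[0] < 3:
            raise InvalidArgumentError(
                "a landscape needs at least 3 sites (distance-matrix "
                "regression needs >= 3 site pairs)"
            )
        if len(self.site_ids) != S.shape[0]:
            raise InvalidArgumentError("site_ids length must match row count")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "E", E)
        if self.sigma_ES is None:
            object.__setattr__(self, "sigma_ES", realized_sigma_es(E, S))
        else:
            object.__setattr__(self, "sigma_ES", np.asarray(self.sigma_ES, dtype=float))

    @property
    def n_sites(self) -> int:
        return self.S.shape[0]

    @property
    def D_S(self) -> int:
        return self.S.shape[1]

    @property
    def D_E(self) -> int:
        return self.E.shape[1]


def realized_sigma_es(E: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Sample covariance matrix (D_E x D_S) between E and S columns."""
    Ec = E - E.mean(axis=0)
    Sc = S - S.mean(axis=0)
    return Ec.T @ Sc / E.shape[0]


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=_STD_DDOF)
    if np.any(sd == 0):
        raise InvalidArgumentError("constant column cannot be z-scored")
    return (x - mu) / sd


def _orthonormalize_columns(X: np.ndarray) -> np.ndarray:
    """Gram-Schmidt: center each column and remove projections onto the
    previous ones, then scale to sd 1. Columns end up with exactly zero
    mutual sample covariance."""
    n, k = X.shape
    out = np.empty_like(X, dtype=float)
    for j in range(k):
        v = X[:, j] - X[:, j].mean()
        for i in range(j):
            v = v - (v @ out[:, i]) / (out[:, i] @ out[:, i]) * out[:, i]
        sd = v.std(ddof=_STD_DDOF)
        if sd < 1e-12:
            raise InvalidArgumentError(
                "degenerate site coordinates: columns are collinear"
            )
        out[:, j] = v / sd
    return out


def generate_landscape(
    n_sites: int,
    sigma_es_target: float,
    D_S: int = 2,
    D_E: int = 2,
    seed: int | np.random.Generator = 0,
) -> Landscape:
    """Generate ``n_sites`` random sites with exact environment-space covariance.

    Spatial columns are drawn from a standard normal and orthonormalized
    (zero mutual sample covariance, mean 0, sd 1). Environmental axis
    *i* is built as ``rho * S_i + sqrt(1 - rho^2) * noise``, where the
    noise vector is orthogonalized against every spatial column, so the
    realized cov(E_i, S_i) equals ``sigma_es_target`` exactly and
    cov(E_i, S_j) = 0 exactly for i != j.

    Parameters
    ----------
    n_sites : int
        Number of local sites (>= 3).
    sigma_es_target : float
        Target covariance in [0, 1). Values >= 1 are rejected: with
        environment perfectly collinear with space, variance
        partitioning cannot separate the two.
    D_S, D_E : int
        Spatial / environmental dimensionality; must be equal
        (environmental axis i pairs with spatial axis i).
    seed : int or numpy Generator
        Source of randomness.
    """
    if n_sites < 3:
        raise InvalidArgumentError("n_sites must be >= 3")
    if not (0.0 <= sigma_es_target < 1.0):
        raise InvalidArgumentError("sigma_es_target must be in [0, 1)")
    if D_E != D_S:
        raise InvalidArgumentError("D_E must equal D_S (axis i pairs with axis i)")
    if n_sites <= 2 * D_S:
        raise InvalidArgumentError(
            "need n_sites > 2 * D_S to orthogonalize noise against space"
        )
    rng = np.random.default_rng(seed)

    S = _orthonormalize_columns(rng.standard_normal((n_sites, D_S)))

    rho = float(sigma_es_target)
    E = np.empty((n_sites, D_E))
    for i in range(D_E):
        noise = rng.standard_normal(n_sites)
        noise = noise - noise.mean()
        for j in range(D_S):
            noise = noise - (noise @ S[:, j]) / (S[:, j] @ S[:, j]) * S[:, j]
        sd = noise.std(ddof=_STD_DDOF)
        if sd < 1e-12:  # astronomically unlikely; regenerate deterministically
            noise = rng.standard_normal(n_sites)
            noise = noise - noise.mean()
            for j in range(D_S):
                noise = noise - (noise @ S[:, j]) / (S[:, j] @ S[:, j]) * S[:, j]
            sd = noise.std(ddof=_STD_DDOF)
        noise /= sd
        E[:, i] = rho * S[:, i] + np.sqrt(1.0 - rho**2) * noise

    site_ids = [f"site{k + 1}" for k in range(n_sites)]
    return Landscape(site_ids=site_ids, S=S, E=E)


# ---------------------------------------------------------------------------
# Sites table I/O


def write_sites_csv(landscape: Landscape, path) -> None:
    cols = {"site_id": landscape.site_ids}
    for j in range(landscape.D_S):
        cols[f"S{j + 1}"] = landscape.S[:, j]
    for i in range(landscape.D_E):
        cols[f"E{i + 1}"] = landscape.E[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_sites_csv(path, standardize: bool = True) -> Landscape:
    """Read a user sites table and report its realized sigma_ES.

    Expected columns: ``site_id``, ``S1..S{D_S}``, ``E1..E{D_E}``.
    User-supplied coordinates are z-scored by default so that distances
    and covariances are on the scale the model assumes.
    """
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'site_id'")
    s_cols = sorted((c for c in df.columns if c.startswith("S") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    e_cols = sorted((c for c in df.columns if c.startswith("E") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    if not s_cols or not e_cols:
        raise SchemaError(f"{path}: need S1.. and E1.. coordinate columns")
    S = df[s_cols].to_numpy(dtype=float)
    E = df[e_cols].to_numpy(dtype=float)
    if np.isnan(S).any() or np.isnan(E).any():
        bad = df[df[s_cols + e_cols].isna().any(axis=1)].index[0]
        raise SchemaError(f"{path}: non-numeric or missing value at row {bad + 2}")
    if standardize:
        S, E = _zscore(S), _zscore(E)
    return Landscape(site_ids=[str(x) for x in df["site_id"]], S=S, E=E)
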