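"""Variance partitioning and multiple regression on distance matrices.

Variation in a beta-diversity matrix is regressed on the pairwise
spatial and environmental distances between sites and decomposed into
four fractions via unadjusted R-squared from three ordinary
least-squares fits (space alone, environment alone, both):

    space_only = R2_SE - R2_E
    env_only   = R2_SE - R2_S
    shared     = R2_S + R2_E - R2_SE
    residual   = 1 - R2_SE

The unique fractions and the residual are non-negative by construction;
the shared fraction may be negative (suppression). All four sum to 1.
No permutation tests are computed: the framework works with fraction
magnitudes, not p-values.

Rates of compositional turnover are the partial regression slopes of
the beta response on both distance vectors jointly (multiple regression
on distance matrices, MRM). For bounded similarity-type responses the
regression uses similarity orientation (1 - dissimilarity for BC), so
more negative slopes mean faster distance decay of similarity; PW and
NN enter raw.

All pair vectors use the canonical lexicographic order (site_a <
site_b), matching scipy's condensed distance ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .betadiv import BetaMatrix
from .errors import InvalidArgumentError, UndefinedPartitionError
from .landscape import Landscape

__all__ = [
    "VarPartFractions",
    "SlopePair",
    "pairwise_predictor_distances",
    "partition_variance",
    "mrm_slopes",
]


@dataclass(frozen=True)
class VarPartFractions:
    env_only: float
    space_only: float
    shared: float
    residual: float

    def __post_init__(self) -> None:
        total = self.env_only + self.space_only + self.shared + self.residual
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError("fractions must sum to 1")


@dataclass(frozen=True)
class SlopePair:
    spatial_slope: float
    environmental_slope: float
    orientation: str = "similarity"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.spatial_slope) and np.isfinite(self.environmental_slope)):
            raise InvalidArgumentError("slopes must be finite")


def pairwise_predictor_distances(
    landscape: Landscape,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean inter-site distance vectors for space and environment.

    Returned in canonical pair order over the N(N-1)/2 site pairs.
    """
    if landscape.n_sites < 3:
        raise InvalidArgumentError("need at least 3 sites")
    return pdist(landscape.S), pdist(landscape.E)


def _as_pair_vector(beta: BetaMatrix | np.ndarray) -> np.ndarray:
    if isinstance(beta, BetaMatrix):
        return beta.condensed()
    arr = np.asarray(beta, dtype=float)
    if arr.ndim == 2:
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]
    return arr


def _zero_variance(y: np.ndarray) -> bool:
    """Treat float-noise-only spread as zero variance: R^2 on pure
    rounding noise is meaningless (a fully saturated beta matrix at
    extreme process strengths differs across pairs only at ~1e-16)."""
    return np.ptp(y) <= 1e-9 * max(1.0, float(np.abs(y).max()))


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """Unadjusted R^2 of an OLS fit with intercept."""
    Xd = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / ss_tot


def partition_variance(
    beta: BetaMatrix | np.ndarray,
    sdist: np.ndarray,
    edist: np.ndarray,
    adjusted: bool = False,
) -> VarPartFractions:
    """Partition beta-diversity variance into space/environment fractions.

    R-squared is invariant under affine transforms of the response, so
    the fractions do not depend on similarity vs dissimilarity
    orientation. ``adjusted=True`` switches to Ezekiel-adjusted
    R-squared (non-default).
    """
    y = _as_pair_vector(beta)
    sdist = np.asarray(sdist, dtype=float)
    edist = np.asarray(edist, dtype=float)
    if not (len(y) == len(sdist) == len(edist)):
        raise InvalidArgumentError("pair vectors must have equal length")
    if _zero_variance(y):
        raise UndefinedPartitionError(
            "beta-diversity response has zero variance; partition undefined"
        )

    def r2(X: np.ndarray) -> float:
        raw = _r_squared(y, X)
        if not adjusted:
            return raw
        n, p = len(y), X.shape[1] if X.ndim == 2 else 1
        return 1.0 - (1.0 - raw) * (n - 1) / (n - p - 1)

    r2_s = r2(sdist[:, None])
    r2_e = r2(edist[:, None])
    r2_se = r2(np.column_stack([sdist, edist]))
    env_only = r2_se - r2_s
    space_only = r2_se - r2_e
    shared = r2_s + r2_e - r2_se
    residual = 1.0 - r2_se
    # numerical guard: unique fractions are >= 0 in exact arithmetic
    env_only = max(env_only, 0.0) if env_only > -1e-12 else env_only
    space_only = max(space_only, 0.0) if space_only > -1e-12 else space_only
    shared = 1.0 - env_only - space_only - residual
    return VarPartFractions(
        env_only=env_only, space_only=space_only, shared=shared, residual=residual
    )


def mrm_slopes(
    beta: BetaMatrix | np.ndarray,
    sdist: np.ndarray,
    edist: np.ndarray,
) -> SlopePair:
    """Partial regression slopes of beta-diversity on both distances.

    Bounded metrics are regressed in similarity orientation (1 - value
    for dissimilarity-oriented BC; SOR already is a similarity); PW and
    NN are regressed raw. When a bare vector/matrix is passed instead of
    a BetaMatrix the response is used as given.
    """
    y = _as_pair_vector(beta)
    orientation = "as-given"
    if isinstance(beta, BetaMatrix):
        if beta.metric in ("BC", "tax_SOR", "phy_SOR", "fun_SOR"):
            orientation = "similarity"
            if beta.orientation == "dissimilarity":
                y = 1.0 - y
        else:
            orientation = "raw"
    sdist = np.asarray(sdist, dtype=float)
    edist = np.asarray(edist, dtype=float)
    if _zero_variance(y):
        raise UndefinedPartitionError(
            "beta-diversity response has zero variance; slopes undefined"
        )
    # centered normal equations; a zero-variance predictor gets slope 0
    # rather than an arbitrary minimum-norm split with the intercept
    slopes = np.zeros(2)
    X = np.column_stack([sdist, edist])
    keep = X.std(axis=0) > 0
    if keep.any():
        Xc = X[:, keep] - X[:, keep].mean(axis=0)
        coef, _, _, _ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        slopes[keep] = coef
    return SlopePair(
        spatial_slope=float(slopes[0]),
        environmental_slope=float(slopes[1]),
        orientation=orientation,
    )
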