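"""Local community assembly by probabilistic sampling of the regional pool.

Each site draws ``J`` individuals with replacement from the regional
species pool. A species' incidence probability at a site is proportional
to the product of (i) its global relative abundance, (ii) a Gaussian
dispersal kernel evaluated at the Euclidean distance between its range
centroid and the site's spatial position (variance ``d``), and (iii) a
Gaussian niche function evaluated at the Euclidean distance between its
environmental optimum and the site's environment (variance ``n``).

At extreme process strength (n or d = 1e-4) the raw Gaussian weights
underflow (exp of order -5000 for z-scored distances), so probabilities
are computed in log space with the per-site maximum subtracted before
exponentiation and renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .evolution import ProcessParams, SpeciesPool
from .landscape import Landscape

__all__ = ["CommunityMatrix", "incidence_probabilities", "assemble_communities"]


@dataclass
class CommunityMatrix:
    """Site x species individual counts, every row summing to J."""

    counts: np.ndarray
    site_ids: list[str]
    species_ids: list[str]
    J: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidArgumentError("counts must be 2-D (sites x species)")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        if not np.all(self.counts.sum(axis=1) == self.J):
            raise InvalidArgumentError("every row must sum to J")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def relative_abundances(self) -> np.ndarray:
        """p_ik: within-site relative abundances (rows sum to 1)."""
        return self.counts / float(self.J)

    @property
    def community_weights(self) -> np.ndarray:
        """P_k: each site's share of all individuals (uniform at fixed J)."""
        tot = self.counts.sum()
        return self.counts.sum(axis=1) / tot

    @property
    def richness(self) -> np.ndarray:
        """S_k: number of species present at each site."""
        return (self.counts > 0).sum(axis=1)


def _log_weights(
    pool: SpeciesPool, landscape: Landscape, params: ProcessParams
) -> np.ndarray:
    """Unnormalized log incidence weights, shape (n_sites, n_species)."""
    if pool.F is None:
        raise InvalidArgumentError("species pool has no abundances (F is None)")
    # squared Euclidean distances site x species, over all axes
    d2_space = (
        ((landscape.S[:, None, :] - pool.R[None, :, :]) ** 2).sum(axis=2)
    )
    d2_env = ((landscape.E[:, None, :] - pool.T[None, :, :]) ** 2).sum(axis=2)
    return (
        np.log(pool.F)[None, :]
        - d2_space / (2.0 * params.d)
        - d2_env / (2.0 * params.n)
    )


def _normalize_log(logw: np.ndarray) -> np.ndarray:
    """Exponentiate log weights row-wise after subtracting the row max."""
    m = logw.max(axis=-1, keepdims=True)
    if np.any(~np.isfinite(m)):
        raise DegenerateInputError("all incidence log-weights are -inf for a site")
    w = np.exp(logw - m)
    return w / w.sum(axis=-1, keepdims=True)


def incidence_probabilities(
    pool: SpeciesPool,
    landscape: Landscape,
    params: ProcessParams,
    site_index: int,
) -> np.ndarray:
    """Normalized incidence probabilities p*_ik over species for one site."""
    logw = _log_weights(pool, landscape, params)[site_index]
    return _normalize_log(logw)


def assemble_communities(
    pool: SpeciesPool,
    landscape: Landscape,
    params: ProcessParams,
    J: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> CommunityMatrix:
    """Assemble every site independently by a multinomial draw of size J.

    Equivalent to J categorical draws with replacement per site, with
    incidence probabilities held fixed during assembly.
    """
    if J < 1:
        raise InvalidArgumentError("J must be >= 1")
    rng = np.random.default_rng(seed)
    probs = _normalize_log(_log_weights(pool, landscape, params))
    counts = np.empty((landscape.n_sites, pool.n_species), dtype=np.int64)
    for k in range(landscape.n_sites):
        counts[k] = rng.multinomial(J, probs[k])
    return CommunityMatrix(
        counts=counts,
        site_ids=list(landscape.site_ids),
        species_ids=list(pool.species_ids),
        J=J,
    )


def assemble_fixed_richness(
    pool: SpeciesPool,
    landscape: Landscape,
    params: ProcessParams,
    target_richness: int,
    seed: int | np.random.Generator = 0,
    max_draws: int = 10_000_000,
) -> CommunityMatrix:
    """Alternative assembly: sample until a fixed species richness is reached.

    Individuals are drawn one at a time per site until ``target_richness``
    distinct species are present; site totals then differ, so rows are
    padded conceptually by stopping at the draw that reaches the target.
    Exposed as the configurable alternative to fixed-J assembly; not
    used by the default pipeline.
    """
    if target_richness < 1 or target_richness > pool.n_species:
        raise InvalidArgumentError("target_richness out of range")
    rng = np.random.default_rng(seed)
    probs = _normalize_log(_log_weights(pool, landscape, params))
    rows = []
    J_max = 0
    for k in range(landscape.n_sites):
        counts = np.zeros(pool.n_species, dtype=np.int64)
        seen = 0
        for _ in range(max_draws):
            i = rng.choice(pool.n_species, p=probs[k])
            if counts[i] == 0:
                seen += 1
            counts[i] += 1
            if seen >= target_richness:
                break
        else:
            raise DegenerateInputError(
                f"site {landscape.site_ids[k]}: target richness not reached "
                f"within {max_draws} draws"
            )
        rows.append(counts)
        J_max = max(J_max, int(counts.sum()))
    counts = np.vstack(rows)
    # rows have unequal totals by construction; J records the largest
    cm = CommunityMatrix.__new__(CommunityMatrix)
    cm.counts = counts
    cm.site_ids = list(landscape.site_ids)
    cm.species_ids = list(pool.species_ids)
    cm.J = J_max
    return cm
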