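"""Global relative abundances for the regional species pool.

Species abundances in the regional pool follow a lognormal species
abundance distribution (SAD). Drawn abundance values are assigned to
species by a uniform random permutation — each value used exactly once —
so there is no phylogenetic or trait signal in abundance: closely
related species are no more likely than distant ones to have similar
global abundances.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .evolution import SpeciesPool

__all__ = ["assign_abundances", "with_abundances"]


def assign_abundances(
    n_species: int,
    sad_meanlog: float = 0.0,
    sad_sdlog: float = 1.0,
    seed: int | np.random.Generator = 0,
    uniform: bool = False,
) -> np.ndarray:
    """Draw a relative-abundance vector F for ``n_species`` species.

    Draws ``n_species`` lognormal deviates (or uniform deviates when
    ``uniform=True``), normalizes them to sum to 1, and assigns them to
    species positions in random order. Returns F with F_i > 0 and
    sum(F) == 1.
    """
    if n_species < 1:
        raise InvalidArgumentError("n_species must be >= 1")
    if sad_sdlog <= 0:
        raise InvalidArgumentError("sad_sdlog must be > 0")
    rng = np.random.default_rng(seed)
    if uniform:
        values = rng.uniform(0.0, 1.0, size=n_species)
        values = np.maximum(values, np.finfo(float).tiny)
    else:
        values = rng.lognormal(mean=sad_meanlog, sigma=sad_sdlog, size=n_species)
    values = values / values.sum()
    return values[rng.permutation(n_species)]


def with_abundances(
    pool: SpeciesPool,
    sad_meanlog: float = 0.0,
    sad_sdlog: float = 1.0,
    seed: int | np.random.Generator = 0,
    uniform: bool = False,
) -> SpeciesPool:
    """Return a copy of ``pool`` with F filled from the SAD."""
    F = assign_abundances(pool.n_species, sad_meanlog, sad_sdlog, seed, uniform)
    return SpeciesPool(
        phylogeny=pool.phylogeny,
        T=pool.T,
        R=pool.R,
        F=F,
        species_ids=list(pool.species_ids),
    )
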