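"""Process-space grid, expectation surfaces and (n, d) inference.

Expectations are generated on a logarithmic grid of process strengths:
for every (niche breadth n, dispersal breadth d) cell, replicate
simulations run the full generative chain (landscape -> phylogeny ->
trait/range evolution -> abundances -> assembly -> beta-diversity ->
variance partitioning) and the per-cell means of the four variance
fractions, the two MRM slopes and local richness form the expectation
surfaces. Surfaces are bilinearly interpolated on the (log10 n, log10 d)
plane; empirical variance-partitioning values are matched against an
interpolated surface within a tolerance band, giving a boolean region
of plausible process strengths per (metric, component). Intersecting
regions across metrics narrows the inference; the true (n, d) must lie
in the intersection.

Each replicate draws its random stream from the master seed keyed by
(cell index, replicate index), so any single replicate is reproducible
in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .assembly import CommunityMatrix, assemble_communities
from .betadiv import METRICS, BetaMatrix, all_beta_matrices
from .errors import BetaprocError, InvalidArgumentError
from .evolution import (
    ProcessParams,
    SpeciesPool,
    build_cov_matrix,
    evolve_pool,
    simulate_tree,
)
from .landscape import Landscape, generate_landscape
from .pool import with_abundances
from .varpart import mrm_slopes, pairwise_predictor_distances, partition_variance

__all__ = [
    "GridConfig",
    "ProcessSurface",
    "InterpolatedSurface",
    "InferenceRegion",
    "default_process_values",
    "simulate_replicate",
    "run_grid",
    "interpolate_surface",
    "quadrant_consistency",
    "infer_region",
    "intersect_regions",
    "default_tolerance",
]

logger = logging.getLogger("betaproc")

COMPONENTS = ("env_only", "space_only", "shared", "residual")
RESPONSES = COMPONENTS + ("spatial_slope", "environmental_slope", "richness")


def default_process_values() -> np.ndarray:
    """Eleven log-spaced process strengths from 1e-4 to 10 (step 10^0.5)."""
    return 10.0 ** np.arange(-4.0, 1.01, 0.5)


@dataclass
class GridConfig:
    """Everything a grid run needs; defaults are the standard scenario.

    20 sites with environment-space covariance 0.7 in two spatial and
    two environmental dimensions; a 500-species pure-birth phylogeny
    (birth 0.1, death 0); lognormal SAD; 10,000 individuals per site;
    an 11 x 11 process grid from 1e-4 to 10.
    """

    n_values: np.ndarray = field(default_factory=default_process_values)
    d_values: np.ndarray = field(default_factory=default_process_values)
    replicates: int = 100
    n_sites: int = 20
    sigma_es: float = 0.7
    D_S: int = 2
    D_E: int = 2
    n_species: int = 500
    birth: float = 0.1
    death: float = 0.0
    sad_meanlog: float = 0.0
    sad_sdlog: float = 1.0
    uniform_sad: bool = False
    J: int = 10_000
    metrics: tuple[str, ...] = METRICS
    functional_distance: str = "dendrogram"
    master_seed: int = 0
    fixed_landscape: bool = False

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=float)
        self.d_values = np.asarray(self.d_values, dtype=float)
        if np.any(np.diff(self.n_values) <= 0) or np.any(np.diff(self.d_values) <= 0):
            raise InvalidArgumentError("process grids must be sorted ascending")
        if np.any(self.n_values <= 0) or np.any(self.d_values <= 0):
            raise InvalidArgumentError("process strengths must be positive")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")


@dataclass
class ProcessSurface:
    """Per-cell, per-metric mean responses plus the per-replicate records."""

    means: pd.DataFrame  # index (n, d, metric); columns RESPONSES + completed
    records: pd.DataFrame  # one row per (cell, replicate, metric)
    n_values: np.ndarray
    d_values: np.ndarray
    replicates: int
    valid: np.ndarray  # (len n, len d) bool: <= 50% failures
    stds: pd.DataFrame | None = None  # replicate sd per cell, same index as means

    def cell_mean(self, n: float, d: float, metric: str, response: str) -> float:
        return float(self.means.loc[(n, d, metric), response])


def _replicate_rng(master_seed: int, cell_index: int, rep_index: int):
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index, rep_index))
    return np.random.default_rng(ss)


def simulate_replicate(
    params: ProcessParams,
    config: GridConfig,
    rng: np.random.Generator,
    landscape: Landscape | None = None,
) -> tuple[Landscape, SpeciesPool, CommunityMatrix, dict[str, BetaMatrix]]:
    """Run one full replicate of the generative chain at (n, d)."""
    if landscape is None:
        landscape = generate_landscape(
            config.n_sites, config.sigma_es, config.D_S, config.D_E, rng
        )
    tree = simulate_tree(config.n_species, config.birth, config.death, rng)
    cov = build_cov_matrix(params, landscape)
    pool = evolve_pool(tree, cov, rng)
    pool = with_abundances(
        pool, config.sad_meanlog, config.sad_sdlog, rng, config.uniform_sad
    )
    comm = assemble_communities(pool, landscape, params, config.J, rng)
    betas = all_beta_matrices(
        comm,
        tree=tree,
        traits=pool.T,
        metrics=config.metrics,
        functional_distance=config.functional_distance,
    )
    return landscape, pool, comm, betas


def replicate_records(
    params: ProcessParams,
    config: GridConfig,
    rng: np.random.Generator,
    landscape: Landscape | None = None,
) -> list[dict]:
    """Variance fractions, slopes and richness for one replicate."""
    landscape, pool, comm, betas = simulate_replicate(params, config, rng, landscape)
    sdist, edist = pairwise_predictor_distances(landscape)
    richness = float(comm.richness.mean())
    rows = []
    for metric, bm in betas.items():
        row = {"metric": metric, "richness": richness}
        try:
            fr = partition_variance(bm, sdist, edist)
            sl = mrm_slopes(bm, sdist, edist)
            row.update(
                env_only=fr.env_only,
                space_only=fr.space_only,
                shared=fr.shared,
                residual=fr.residual,
                spatial_slope=sl.spatial_slope,
                environmental_slope=sl.environmental_slope,
                failed=False,
            )
        except BetaprocError as exc:
            logger.warning("metric %s undefined for a replicate: %s", metric, exc)
            row.update(
                {c: np.nan for c in COMPONENTS},
                spatial_slope=np.nan,
                environmental_slope=np.nan,
                failed=True,
            )
        rows.append(row)
    return rows


def run_grid(config: GridConfig) -> ProcessSurface:
    """Run the replicate grid over process space and aggregate cell means.

    Replicate failures (e.g. a zero-variance beta response at extreme
    process strengths) are logged with their seed key and recorded as
    NaN; a cell-metric with more than 50% failed replicates is flagged
    invalid.
    """
    fixed_land = None
    if config.fixed_landscape:
        fixed_land = generate_landscape(
            config.n_sites,
            config.sigma_es,
            config.D_S,
            config.D_E,
            np.random.default_rng(
                np.random.SeedSequence(config.master_seed, spawn_key=(2**20,))
            ),
        )

    all_rows: list[dict] = []
    n_n, n_d = len(config.n_values), len(config.d_values)
    for ci, n in enumerate(config.n_values):
        for cj, d in enumerate(config.d_values):
            cell_index = ci * n_d + cj
            params = ProcessParams(n=float(n), d=float(d))
            for r in range(config.replicates):
                rng = _replicate_rng(config.master_seed, cell_index, r)
                try:
                    rows = replicate_records(params, config, rng, fixed_land)
                except BetaprocError as exc:
                    logger.warning(
                        "replicate failed at n=%g d=%g rep=%d "
                        "(seed key master=%d cell=%d rep=%d): %s",
                        n, d, r, config.master_seed, cell_index, r, exc,
                    )
                    rows = [
                        {
                            "metric": m,
                            "richness": np.nan,
                            **{c: np.nan for c in COMPONENTS},
                            "spatial_slope": np.nan,
                            "environmental_slope": np.nan,
                            "failed": True,
                        }
                        for m in config.metrics
                    ]
                for row in rows:
                    row.update(n=float(n), d=float(d), cell_i=ci, cell_j=cj,
                               replicate=r)
                all_rows.extend(rows)

    records = pd.DataFrame(all_rows)
    grouped = records.groupby(["n", "d", "metric"], sort=True)
    means = grouped[list(RESPONSES)].mean()
    stds = grouped[list(RESPONSES)].std(ddof=1)
    means["completed"] = grouped["failed"].apply(lambda f: int((~f).sum()))

    fail_frac = (
        records.groupby(["cell_i", "cell_j"])["failed"].mean().unstack(fill_value=1.0)
    )
    valid = np.ones((n_n, n_d), dtype=bool)
    for (ci, cj), frac in fail_frac.stack().items():
        valid[int(ci), int(cj)] = frac <= 0.5

    return ProcessSurface(
        means=means,
        records=records,
        n_values=config.n_values,
        d_values=config.d_values,
        replicates=config.replicates,
        valid=valid,
        stds=stds,
    )


# ---------------------------------------------------------------------------
# Interpolation


@dataclass
class InterpolatedSurface:
    """Dense bilinear lattice per (metric, response) on the log-log plane.

    ``stds`` carries the interpolated per-cell replicate standard
    deviations when the source surface recorded them; region matching
    uses them to widen tolerance bands where the expectation itself is
    noisy.
    """

    log_n: np.ndarray
    log_d: np.ndarray
    values: dict[tuple[str, str], np.ndarray]  # (metric, response) -> 2-D
    stds: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def lattice_value(self, metric: str, response: str, n: float, d: float) -> float:
        i = int(np.argmin(np.abs(self.log_n - np.log10(n))))
        j = int(np.argmin(np.abs(self.log_d - np.log10(d))))
        return float(self.values[(metric, response)][i, j])


def interpolate_surface(
    surface: ProcessSurface,
    resolution: int = 61,
    metrics: Sequence[str] | None = None,
    responses: Sequence[str] = RESPONSES,
) -> InterpolatedSurface:
    """Bilinear interpolation of cell means on the (log10 n, log10 d) plane.

    Values at the original grid nodes are reproduced exactly. Invalid
    cells propagate NaN into the surrounding lattice cells, with a
    warning.
    """
    if len(surface.n_values) < 2 or len(surface.d_values) < 2:
        raise InvalidArgumentError("interpolation needs at least a 2x2 grid")
    if not surface.valid.all():
        warnings.warn(
            "invalid cells present; interpolation restricted to valid subregions",
            stacklevel=2,
        )
    log_n_nodes = np.log10(surface.n_values)
    log_d_nodes = np.log10(surface.d_values)
    log_n = np.linspace(log_n_nodes[0], log_n_nodes[-1], resolution)
    log_d = np.linspace(log_d_nodes[0], log_d_nodes[-1], resolution)

    metric_list = (
        list(metrics)
        if metrics is not None
        else sorted(surface.means.index.get_level_values("metric").unique())
    )
    mesh = np.stack(np.meshgrid(log_n, log_d, indexing="ij"), axis=-1)

    def lattice(table: pd.DataFrame, metric: str, response: str) -> np.ndarray:
        grid = (
            table.xs(metric, level="metric")[response]
            .unstack(level="d")
            .reindex(index=surface.n_values, columns=surface.d_values)
            .to_numpy()
        )
        grid = np.where(surface.valid, grid, np.nan)
        interp = RegularGridInterpolator(
            (log_n_nodes, log_d_nodes), grid, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        return interp(mesh)

    out: dict[tuple[str, str], np.ndarray] = {}
    out_std: dict[tuple[str, str], np.ndarray] = {}
    for metric in metric_list:
        for response in responses:
            out[(metric, response)] = lattice(surface.means, metric, response)
            if surface.stds is not None:
                out_std[(metric, response)] = lattice(surface.stds, metric, response)
    return InterpolatedSurface(log_n=log_n, log_d=log_d, values=out, stds=out_std)


# ---------------------------------------------------------------------------
# Quadrant consistency


def quadrant_consistency(
    records: pd.DataFrame,
    exclude_diagonal: bool = True,
    denominator: str = "evaluated",
) -> pd.DataFrame:
    """Percentage of replicates whose dominant variance component matches
    the dominant process.

    A replicate at (n, d) is consistent when d/n < 1 (dispersal
    limitation stronger) coincides with space_only/env_only > 1, or
    d/n > 1 with space_only/env_only < 1. Cells on the d = n diagonal
    are excluded from the denominator by default (the expected ratio is
    1 there, so neither quadrant applies). Replicates with an undefined
    component ratio (zero or NaN fractions — typically fully saturated
    beta matrices at extreme process strengths) are counted in
    ``excluded``; with ``denominator="evaluated"`` (default) they leave
    the denominator, while ``denominator="all"`` keeps them in it as
    not-consistent — a saturated replicate is itself a case where the
    intuitive expectation fails.
    """
    if denominator not in ("evaluated", "all"):
        raise InvalidArgumentError("denominator must be 'evaluated' or 'all'")
    req = {"n", "d", "metric", "space_only", "env_only"}
    if not req.issubset(records.columns):
        raise InvalidArgumentError(f"records need columns {sorted(req)}")
    out_rows = []
    for metric, sub in records.groupby("metric", sort=True):
        if exclude_diagonal:
            sub = sub[sub["n"] != sub["d"]]
        process_ratio = sub["d"].to_numpy() / sub["n"].to_numpy()
        space = sub["space_only"].to_numpy()
        env = sub["env_only"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            comp_ratio = space / env
        # a zero (or NaN) fraction leaves the component ratio undefined
        defined = (space > 0) & (env > 0) & np.isfinite(comp_ratio)
        # ratio of exactly 1 (ties) sits in neither quadrant: inconsistent
        consistent = ((process_ratio < 1) & (comp_ratio > 1)) | (
            (process_ratio > 1) & (comp_ratio < 1)
        )
        n_eval = int(defined.sum())
        n_cons = int((consistent & defined).sum())
        denom = n_eval if denominator == "evaluated" else len(sub)
        out_rows.append(
            {
                "metric": metric,
                "percent_consistent": 100.0 * n_cons / denom if denom else np.nan,
                "evaluated": n_eval,
                "excluded": int(len(sub) - n_eval),
            }
        )
    return pd.DataFrame(out_rows).set_index("metric")


# ---------------------------------------------------------------------------
# Region inference


def default_tolerance(empirical_value: float) -> float:
    """Scale-aware matching band, bounded below so near-zero fractions
    still admit a region: max(0.25 * |value|, 0.01)."""
    return max(0.25 * abs(empirical_value), 0.01)


@dataclass
class InferenceRegion:
    """Boolean mask of plausible (n, d) over an interpolated lattice."""

    mask: np.ndarray
    log_n: np.ndarray
    log_d: np.ndarray
    matched: list[dict]
    tolerance: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.log_n), len(self.log_d)):
            raise InvalidArgumentError("mask shape must equal lattice shape")

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def contains(self, n: float, d: float) -> bool:
        """Mask value at the lattice node nearest to (n, d)."""
        i = int(np.argmin(np.abs(self.log_n - np.log10(n))))
        j = int(np.argmin(np.abs(self.log_d - np.log10(d))))
        return bool(self.mask[i, j])

    def components(self) -> list[dict]:
        """Connected components with bounding boxes in (n, d) units."""
        labels, n_comp = ndimage.label(self.mask)
        comps = []
        for c in range(1, n_comp + 1):
            ii, jj = np.nonzero(labels == c)
            comps.append(
                {
                    "size": int(ii.size),
                    "n_range": (10.0 ** self.log_n[ii.min()], 10.0 ** self.log_n[ii.max()]),
                    "d_range": (10.0 ** self.log_d[jj.min()], 10.0 ** self.log_d[jj.max()]),
                }
            )
        return comps

    def summary(self) -> dict:
        comps = self.components()
        return {
            "matched": self.matched,
            "n_components": len(comps),
            "components": comps,
            "status": "empty: no consistent process strengths"
            if self.is_empty
            else "ok",
        }


def infer_region(
    surface: ProcessSurface | InterpolatedSurface,
    metric: str,
    component: str,
    empirical_value: float,
    tolerance: float | None = None,
    resolution: int = 61,
    noise_z: float = 2.576,
) -> InferenceRegion:
    """Region of process space matching one empirical fraction.

    The mask is true where |interpolated surface - empirical value| is
    within the matching band. With ``tolerance=None`` the band at each
    lattice point is ``max(default_tolerance(value), noise_z * sd)``,
    where ``sd`` is the interpolated replicate standard deviation of the
    expectation at that point (when the surface recorded one): an
    empirical value is a single realization, so cells whose replicate
    scatter could plausibly have produced it must match. An explicit
    ``tolerance`` is used verbatim with no noise term. An empty region
    is a valid, reportable outcome.
    """
    if isinstance(surface, ProcessSurface):
        surface = interpolate_surface(
            surface, resolution=resolution, metrics=[metric], responses=[component]
        )
    lattice = surface.values[(metric, component)]
    if tolerance is None:
        base = default_tolerance(empirical_value)
        band = np.full_like(lattice, base)
        sd = surface.stds.get((metric, component))
        if sd is not None:
            band = np.fmax(band, noise_z * np.nan_to_num(sd, nan=0.0))
        tol_report = base
    else:
        band = np.full_like(lattice, float(tolerance))
        tol_report = float(tolerance)
    with np.errstate(invalid="ignore"):
        mask = np.abs(lattice - empirical_value) <= band
    mask &= ~np.isnan(lattice)
    return InferenceRegion(
        mask=mask,
        log_n=surface.log_n,
        log_d=surface.log_d,
        matched=[{"metric": metric, "component": component,
                  "value": float(empirical_value), "tolerance": tol_report,
                  "noise_z": noise_z if tolerance is None else 0.0}],
        tolerance=tol_report,
    )


def intersect_regions(regions: Sequence[InferenceRegion]) -> InferenceRegion:
    """Logical AND of region masks (all on the same lattice)."""
    if not regions:
        raise InvalidArgumentError("need at least one region")
    first = regions[0]
    mask = first.mask.copy()
    matched = list(first.matched)
    for r in regions[1:]:
        if not (
            np.array_equal(r.log_n, first.log_n)
            and np.array_equal(r.log_d, first.log_d)
        ):
            raise InvalidArgumentError("regions must share the same lattice")
        mask &= r.mask
        matched.extend(r.matched)
    return InferenceRegion(
        mask=mask, log_n=first.log_n, log_d=first.log_d, matched=matched
    )
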