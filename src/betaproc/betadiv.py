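"""Taxonomic, phylogenetic and functional beta-diversity metrics.

Eight metric variants are computed between pairs of local communities:

``BC``
    Bray-Curtis dissimilarity on within-site relative abundances,
    0.5 * sum_i |p_ik - p_il|. With presence/absence inputs it equals
    one minus the taxonomic Sorensen similarity.
``tax_SOR``
    Classical Sorensen similarity on presence/absence,
    2a / (2a + b + c).
``phy_PW`` / ``fun_PW``
    Abundance-weighted mean pairwise distance between communities,
    sum_i sum_j p_ik p_jl delta_ij, with delta the patristic
    (phylogenetic) or Euclidean trait (functional) distance. A
    between-community analogue of the net relatedness index.
``phy_NN`` / ``fun_NN``
    Abundance-weighted mean nearest-neighbor distance, symmetrized:
    0.5 * [sum_i p_ik min_j delta_ij + sum_j p_jl min_i delta_ij].
    A between-community analogue of the nearest taxon index.
``phy_SOR`` / ``fun_SOR``
    Branch-length Sorensen similarity, 2*B_kl / (B_k + B_l), where B_k
    is the branch length of the subtree spanned by site k's species
    (root-ward to the spanning subtree's root) on the phylogeny or on a
    UPGMA trait dendrogram, and B_kl the branch length shared by both
    spanning subtrees. Ignores abundances.

Functional metrics are computed on a UPGMA dendrogram of Euclidean
trait distances by default: SOR needs the dendrogram's branch lengths,
and PW/NN use its cophenetic distances, so all three functional
variants see the same trait structure. PW and NN do not *require* a
dendrogram — ``functional_distance="traits"`` (or an explicit ``dist``)
switches them to raw Euclidean trait distances.

Every metric is registered in ``METRIC_REGISTRY`` so an alternative
transcription can be plugged in without touching the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .assembly import CommunityMatrix
from .errors import InvalidArgumentError, UndefinedMetricError
from .evolution import Phylogeny

__all__ = [
    "METRICS",
    "ORIENTATION",
    "DistanceMatrix",
    "BetaMatrix",
    "cophenetic_distances",
    "trait_dendrogram",
    "pairwise_metric_PW",
    "pairwise_metric_NN",
    "branch_sorensen",
    "bray_curtis",
    "beta_matrix",
    "all_beta_matrices",
]

METRICS = (
    "BC",
    "tax_SOR",
    "phy_PW",
    "phy_NN",
    "phy_SOR",
    "fun_PW",
    "fun_NN",
    "fun_SOR",
)

#: similarity metrics take the value 1 for identical communities;
#: dissimilarity(-like) metrics take 0 (BC) or the within-community
#: mean distance (PW).
ORIENTATION = {
    "BC": "dissimilarity",
    "tax_SOR": "similarity",
    "phy_PW": "dissimilarity",
    "phy_NN": "dissimilarity",
    "phy_SOR": "similarity",
    "fun_PW": "dissimilarity",
    "fun_NN": "dissimilarity",
    "fun_SOR": "similarity",
}


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric species-species distance matrix with id index."""

    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise InvalidArgumentError("distance matrix must be square")
        if M.shape[0] != len(self.ids):
            raise InvalidArgumentError("ids must match matrix order")
        if not np.allclose(M, M.T, atol=1e-9):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(M)) > 1e-9) or np.any(M < -1e-12):
            raise InvalidArgumentError(
                "distances must be non-negative with zero diagonal"
            )
        object.__setattr__(self, "matrix", M)


@dataclass(frozen=True)
class BetaMatrix:
    """Site x site matrix of one beta-diversity metric."""

    metric: str
    values: np.ndarray
    site_ids: list[str]
    orientation: str

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise InvalidArgumentError("beta matrix must be square")
        if not np.allclose(V, V.T, atol=1e-9):
            raise InvalidArgumentError("beta matrix must be symmetric")
        if self.orientation not in ("similarity", "dissimilarity"):
            raise InvalidArgumentError("orientation must be similarity|dissimilarity")
        object.__setattr__(self, "values", V)

    def condensed(self) -> np.ndarray:
        """Off-diagonal values in canonical (lexicographic) pair order."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Species-space distances


def cophenetic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Patristic distances between all tip pairs of a tree/dendrogram."""
    if tree.n_tips < 2:
        raise InvalidArgumentError("need at least 2 tips")
    return DistanceMatrix(matrix=tree.cophenetic_matrix(), ids=list(tree.tip_labels))


def trait_distances(T: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Euclidean distances between species trait vectors."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != len(ids):
        raise InvalidArgumentError("trait rows must match ids")
    return DistanceMatrix(matrix=squareform(pdist(T)), ids=list(ids))


def trait_dendrogram(
    T: np.ndarray, ids: list[str], method: str = "average"
) -> Phylogeny:
    """Hierarchical clustering of Euclidean trait distances as a tree.

    UPGMA (average linkage) by default; the result is ultrametric with
    tip-to-root depth equal to half the final merge height, so
    cophenetic distances on the dendrogram equal the linkage heights.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    m = T.shape[0]
    if m < 2:
        raise InvalidArgumentError("need at least 2 species")
    if len(ids) != m:
        raise InvalidArgumentError("ids must match trait rows")
    Z = linkage(pdist(T), method=method)
    return linkage_to_phylogeny(Z, ids)


def linkage_to_phylogeny(Z: np.ndarray, ids: list[str]) -> Phylogeny:
    """Convert a scipy linkage matrix into the package tree type.

    Cluster node heights are half the merge distance, so that the
    tip-tip path length through a merge node equals its cophenetic
    distance.
    """
    m = Z.shape[0] + 1
    n_nodes = 2 * m - 1
    height = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for j in range(Z.shape[0]):
        a, b = int(Z[j, 0]), int(Z[j, 1])
        node = m + j
        height[node] = Z[j, 2] / 2.0
        parent[a] = node
        parent[b] = node
    lengths = np.zeros(n_nodes)
    for v in range(n_nodes - 1):  # root is the last cluster
        lengths[v] = height[parent[v]] - height[v]
    labels = {i: str(ids[i]) for i in range(m)}
    return Phylogeny(parent, lengths, labels)


# ---------------------------------------------------------------------------
# Pairwise (two-community) metric forms


def _check_rel(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.sum() <= 0:
        raise UndefinedMetricError(f"community {name} is empty")
    return p


def pairwise_metric_PW(
    p_k: np.ndarray,
    p_l: np.ndarray,
    dist: DistanceMatrix | np.ndarray,
    weights: tuple[float, float] | None = None,
) -> float:
    """Abundance-weighted mean between-community pairwise distance.

    ``weights`` are the relative community abundances (P_k, P_l); for a
    two-community comparison they cancel (the weighted mean over the two
    directions is symmetric), so they are accepted for interface
    completeness but do not change the value. Note PW of a community
    with itself is its within-community mean pairwise distance, not 0.
    """
    p_k = _check_rel(p_k, "k")
    p_l = _check_rel(p_l, "l")
    D = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    return float(p_k @ D @ p_l)


def pairwise_metric_NN(
    p_k: np.ndarray,
    p_l: np.ndarray,
    dist: DistanceMatrix | np.ndarray,
    weights: tuple[float, float] | None = None,
) -> float:
    """Abundance-weighted mean nearest-neighbor distance, symmetrized.

    Each species in community k contributes the minimum distance to any
    species present in l (and vice versa); the two directed means are
    combined with the community-abundance weights (equal by default).
    """
    p_k = _check_rel(p_k, "k")
    p_l = _check_rel(p_l, "l")
    D = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    in_k = p_k > 0
    in_l = p_l > 0
    min_to_l = D[:, in_l].min(axis=1)
    min_to_k = D[:, in_k].min(axis=1)
    term_k = float(p_k @ min_to_l)
    term_l = float(p_l @ min_to_k)
    if weights is None:
        w_k = w_l = 0.5
    else:
        w_k, w_l = weights
        tot = w_k + w_l
        w_k, w_l = w_k / tot, w_l / tot
    return w_k * term_k + w_l * term_l


def _presence_vector(tree: Phylogeny, presence) -> np.ndarray:
    """Coerce a label set or boolean/abundance vector to tip-aligned bool."""
    if isinstance(presence, (set, frozenset, list, tuple)) and all(
        isinstance(x, str) for x in presence
    ):
        pos = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
        out = np.zeros(tree.n_tips, dtype=bool)
        for lbl in presence:
            if lbl not in pos:
                raise InvalidArgumentError(f"unknown tip label {lbl!r}")
            out[pos[lbl]] = True
        return out
    arr = np.asarray(presence)
    if arr.shape != (tree.n_tips,):
        raise InvalidArgumentError("presence vector must align with tips")
    return arr.astype(bool) if arr.dtype != bool else arr


def branch_sorensen(tree: Phylogeny, presence_k, presence_l) -> float:
    """Branch-length Sorensen similarity between two presence sets.

    B_k is the total branch length of the subtree spanning site k's
    species (edges on paths between those tips only, i.e. below the
    spanning subtree's root); B_kl is the length of edges shared by both
    spanning subtrees. When both communities are single species the
    spanning subtrees have no edges; the similarity is then 1 for
    identical sets and 0 otherwise.
    """
    pk = _presence_vector(tree, presence_k)
    pl = _presence_vector(tree, presence_l)
    if not pk.any() or not pl.any():
        raise UndefinedMetricError("empty community in branch Sorensen")
    M = tree.tip_membership().astype(np.int64)
    ck = M @ pk.astype(np.int64)
    cl = M @ pl.astype(np.int64)
    in_k = (ck > 0) & (ck < pk.sum())
    in_l = (cl > 0) & (cl < pl.sum())
    B_k = float(tree.lengths @ in_k)
    B_l = float(tree.lengths @ in_l)
    B_kl = float(tree.lengths @ (in_k & in_l))
    if B_k + B_l == 0.0:
        return 1.0 if np.array_equal(pk, pl) else 0.0
    return 2.0 * B_kl / (B_k + B_l)


def bray_curtis(p_k: np.ndarray, p_l: np.ndarray) -> float:
    """Bray-Curtis dissimilarity of two relative-abundance vectors."""
    p_k = np.asarray(p_k, dtype=float)
    p_l = np.asarray(p_l, dtype=float)
    denom = (p_k + p_l).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(p_k - p_l).sum() / denom)


# ---------------------------------------------------------------------------
# Full site x site matrices (vectorized over all pairs)


def _bc_matrix(P: np.ndarray) -> np.ndarray:
    return squareform(pdist(P, metric="cityblock")) / 2.0


def _tax_sor_matrix(P: np.ndarray) -> np.ndarray:
    A = (P > 0).astype(float)
    shared = A @ A.T
    rich = A.sum(axis=1)
    denom = rich[:, None] + rich[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        S = 2.0 * shared / denom
    return np.nan_to_num(S, nan=1.0)


def _pw_matrix(P: np.ndarray, D: np.ndarray) -> np.ndarray:
    M = P @ D @ P.T
    return (M + M.T) / 2.0  # symmetrize away float noise


def _nn_matrix(P: np.ndarray, D: np.ndarray) -> np.ndarray:
    n_sites = P.shape[0]
    colmin = np.empty((n_sites, P.shape[1]))
    for l in range(n_sites):
        present = P[l] > 0
        if not present.any():
            raise UndefinedMetricError(f"site index {l} is empty")
        colmin[l] = D[:, present].min(axis=1)
    M = P @ colmin.T  # entry (k, l) = sum_i p_ik * min_{j in l} delta_ij
    return (M + M.T) / 2.0


def _branch_sor_matrix(P: np.ndarray, tree: Phylogeny) -> np.ndarray:
    pres = (P > 0)
    n_sites = P.shape[0]
    M = tree.tip_membership().astype(np.float64)
    counts = M @ pres.T  # (n_nodes, n_sites)
    totals = pres.sum(axis=1)
    in_site = (counts > 0) & (counts < totals[None, :])
    B = tree.lengths @ in_site
    out = np.eye(n_sites)
    for k in range(n_sites):
        for l in range(k + 1, n_sites):
            shared = float(tree.lengths @ (in_site[:, k] & in_site[:, l]))
            denom = B[k] + B[l]
            if denom == 0.0:
                v = 1.0 if np.array_equal(pres[k], pres[l]) else 0.0
            else:
                v = 2.0 * shared / denom
            out[k, l] = out[l, k] = v
    return out


MetricFn = Callable[..., np.ndarray]
METRIC_REGISTRY: dict[str, MetricFn] = {}


def beta_matrix(
    metric: str,
    comm: CommunityMatrix,
    tree: Phylogeny | None = None,
    traits: np.ndarray | None = None,
    dist: DistanceMatrix | None = None,
    dendrogram: Phylogeny | None = None,
    functional_distance: str = "dendrogram",
) -> BetaMatrix:
    """Compute one metric for all pairwise community comparisons.

    Phylogenetic metrics need ``tree``; functional metrics need
    ``traits`` (or a precomputed ``dendrogram`` / explicit ``dist``).
    ``functional_distance`` selects the species-distance source for
    functional PW/NN: ``"dendrogram"`` (UPGMA cophenetic, default) or
    ``"traits"`` (raw Euclidean). Distance matrices passed explicitly
    must be aligned with ``comm.species_ids``.
    """
    if metric not in METRICS and metric not in METRIC_REGISTRY:
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    P = comm.relative_abundances
    if np.any(P.sum(axis=1) <= 0):
        raise UndefinedMetricError("empty community row")

    def species_dist(kind: str) -> np.ndarray:
        if dist is not None:
            if list(dist.ids) != list(comm.species_ids):
                order = [dist.ids.index(s) for s in comm.species_ids]
                return dist.matrix[np.ix_(order, order)]
            return dist.matrix
        if kind == "phy":
            if tree is None:
                raise InvalidArgumentError(f"{metric} requires a tree")
            return _aligned_cophenetic(tree, comm.species_ids)
        if functional_distance == "dendrogram" or dendrogram is not None:
            dend = dendrogram
            if dend is None:
                if traits is None:
                    raise InvalidArgumentError(f"{metric} requires traits or dist")
                dend = trait_dendrogram(traits, list(comm.species_ids))
            return _aligned_cophenetic(dend, comm.species_ids)
        if traits is None:
            raise InvalidArgumentError(f"{metric} requires traits or dist")
        return squareform(pdist(np.atleast_2d(traits)))

    if metric in METRIC_REGISTRY:
        values = METRIC_REGISTRY[metric](
            comm=comm, tree=tree, traits=traits, dist=dist, dendrogram=dendrogram
        )
    elif metric == "BC":
        values = _bc_matrix(P)
    elif metric == "tax_SOR":
        values = _tax_sor_matrix(P)
    elif metric in ("phy_PW", "fun_PW"):
        values = _pw_matrix(P, species_dist(metric[:3]))
    elif metric in ("phy_NN", "fun_NN"):
        values = _nn_matrix(P, species_dist(metric[:3]))
    elif metric == "phy_SOR":
        if tree is None:
            raise InvalidArgumentError("phy_SOR requires a tree")
        values = _branch_sor_matrix(_align_comm(P, tree, comm.species_ids), tree)
    else:  # fun_SOR
        dend = dendrogram
        if dend is None:
            if traits is None:
                raise InvalidArgumentError("fun_SOR requires traits or a dendrogram")
            dend = trait_dendrogram(traits, list(comm.species_ids))
        values = _branch_sor_matrix(_align_comm(P, dend, comm.species_ids), dend)
    return BetaMatrix(
        metric=metric,
        values=values,
        site_ids=list(comm.site_ids),
        orientation=ORIENTATION.get(metric, "dissimilarity"),
    )


def _aligned_cophenetic(tree: Phylogeny, species_ids: list[str]) -> np.ndarray:
    D = tree.cophenetic_matrix()
    if list(tree.tip_labels) == list(species_ids):
        return D
    pos = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
    try:
        order = [pos[s] for s in species_ids]
    except KeyError as exc:
        raise InvalidArgumentError(f"species {exc.args[0]!r} missing from tree")
    return D[np.ix_(order, order)]


def _align_comm(P: np.ndarray, tree: Phylogeny, species_ids: list[str]) -> np.ndarray:
    """Reorder community columns into the tree's tip order."""
    if list(tree.tip_labels) == list(species_ids):
        return P
    pos = {s: j for j, s in enumerate(species_ids)}
    try:
        order = [pos[lbl] for lbl in tree.tip_labels]
    except KeyError as exc:
        raise InvalidArgumentError(f"tip {exc.args[0]!r} missing from community")
    return P[:, order]


def all_beta_matrices(
    comm: CommunityMatrix,
    tree: Phylogeny | None = None,
    traits: np.ndarray | None = None,
    metrics: tuple[str, ...] = METRICS,
    functional_distance: str = "dendrogram",
) -> dict[str, BetaMatrix]:
    """Compute a set of metrics sharing precomputed species distances.

    The cophenetic matrix, the trait dendrogram (and its cophenetic
    matrix) and the trait distance matrix are each built at most once;
    this is the path the replicate grid uses.
    """
    if functional_distance not in ("dendrogram", "traits"):
        raise InvalidArgumentError("functional_distance must be dendrogram|traits")
    out: dict[str, BetaMatrix] = {}
    phy_dist: DistanceMatrix | None = None
    fun_dist: DistanceMatrix | None = None
    dend: Phylogeny | None = None

    def need_dend() -> Phylogeny:
        nonlocal dend
        if dend is None:
            if traits is None:
                raise InvalidArgumentError("functional metrics require traits")
            dend = trait_dendrogram(traits, list(comm.species_ids))
        return dend

    for metric in metrics:
        if metric in ("phy_PW", "phy_NN") and phy_dist is None:
            if tree is None:
                raise InvalidArgumentError(f"{metric} requires a tree")
            phy_dist = DistanceMatrix(
                matrix=_aligned_cophenetic(tree, list(comm.species_ids)),
                ids=list(comm.species_ids),
            )
        if metric in ("fun_PW", "fun_NN") and fun_dist is None:
            if functional_distance == "dendrogram":
                fun_dist = DistanceMatrix(
                    matrix=_aligned_cophenetic(need_dend(), list(comm.species_ids)),
                    ids=list(comm.species_ids),
                )
            else:
                if traits is None:
                    raise InvalidArgumentError(f"{metric} requires traits")
                fun_dist = trait_distances(traits, list(comm.species_ids))
        out[metric] = beta_matrix(
            metric,
            comm,
            tree=tree,
            traits=traits,
            dist=phy_dist if metric in ("phy_PW", "phy_NN")
            else fun_dist if metric in ("fun_PW", "fun_NN")
            else None,
            dendrogram=need_dend() if metric == "fun_SOR" else None,
            functional_distance=functional_distance,
        )
    return out
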