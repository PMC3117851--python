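"""Regional phylogeny and joint evolution of traits and range centroids.

The regional species pool is a birth-death phylogeny on which each
species' environmental optima (its functional traits, ``T``) and range
centroid coordinates (``R``) evolve jointly by multivariate Brownian
motion. The per-unit-time increment covariance is the idealized
trait-space covariance matrix: unit variances, zero trait-trait and
space-space covariances, and trait-i x space-j entries given by an
additive model combining dispersal limitation and environmental
filtering,

    sigma_TR(i, j) = (exp(-d) + exp(-n_i) * sigma_ES(i, j)) / (2 * D_S)

where ``n`` is the variance of the Gaussian niche function (large n =
broad niches = weak filtering), ``d`` the variance of the Gaussian
dispersal kernel (large d = weak dispersal limitation), and
``sigma_ES(i, j)`` the covariance between environmental axis i and
spatial axis j across sites. Under extreme dispersal limitation the
dispersal term exp(-d) -> 1 (traits track space because lineages cannot
move); with unlimited dispersal it -> 0. The filtering term is a
declining fraction of sigma_ES: even infinitely strong filtering can
couple traits to space only as much as the environment itself is
spatially structured. The 2*D_S denominator keeps the covariance summed
across dimensions within [0, 1] for z-scored axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidArgumentError, ModelInfeasibleError
from .landscape import Landscape

__all__ = [
    "Phylogeny",
    "ProcessParams",
    "TraitSpaceCov",
    "SpeciesPool",
    "simulate_tree",
    "eq5_covariance",
    "build_cov_matrix",
    "evolve_pool",
]


# ---------------------------------------------------------------------------
# Phylogeny container


class Phylogeny:
    """Rooted tree with branch lengths, backed by flat arrays.

    Nodes are integers ``0..n_nodes-1``; ``parent[v]`` is the parent of
    ``v`` (root has parent -1) and ``lengths[v]`` is the length of the
    edge above ``v`` (0 for the root). Tips carry unique string labels.
    The array layout keeps cophenetic distances, branch-membership masks
    and Brownian simulation O(n^2) with vectorized inner loops, which
    matters for 500-tip pools inside replicate grids.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        tip_labels_by_node: dict[int, str],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        n = self.parent.size
        if self.lengths.size != n:
            raise InvalidArgumentError("parent and lengths must have equal size")
        if np.any(self.lengths < -1e-12):
            raise InvalidArgumentError("branch lengths must be non-negative")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise InvalidArgumentError("tree must have exactly one root")
        self.root = int(roots[0])

        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)

        self.tips = np.array(
            [v for v in range(n) if not self.children[v]], dtype=np.int64
        )
        labels = [tip_labels_by_node.get(int(v)) for v in self.tips]
        if any(l is None for l in labels):
            raise InvalidArgumentError("every tip needs a label")
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("tip labels must be unique")
        self.tip_labels: list[str] = [str(l) for l in labels]

        # preorder: parents before children
        order = np.empty(n, dtype=np.int64)
        stack = [self.root]
        i = 0
        while stack:
            v = stack.pop()
            order[i] = v
            i += 1
            stack.extend(self.children[v])
        self.preorder = order

    # -- basic properties ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tips.size

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        return depth

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.node_depths()[self.tips]
        return bool(np.ptp(d) <= tol)

    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- derived structures --------------------------------------------------

    def cophenetic_matrix(self) -> np.ndarray:
        """Patristic distance between every pair of tips.

        Returns a (n_tips, n_tips) matrix ordered like ``tip_labels``;
        entry (i, j) is the sum of branch lengths on the path between
        tips i and j: depth_i + depth_j - 2 * depth of their MRCA.
        Filled per internal node by outer-block assignment over the tip
        sets of distinct child subtrees.
        """
        depth = self.node_depths()
        tip_pos = {int(v): i for i, v in enumerate(self.tips)}
        n = self.n_tips
        D = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for v in self.preorder[::-1]:  # postorder
            if not self.children[v]:
                tipsets[v] = np.array([tip_pos[int(v)]], dtype=np.int64)
                continue
            blocks = [tipsets.pop(c) for c in self.children[v]]
            for a in range(len(blocks)):
                for b in range(a + 1, len(blocks)):
                    A, B = blocks[a], blocks[b]
                    da = depth[self.tips[A]]
                    db = depth[self.tips[B]]
                    block = da[:, None] + db[None, :] - 2.0 * depth[v]
                    D[np.ix_(A, B)] = block
                    D[np.ix_(B, A)] = block.T
            tipsets[v] = np.concatenate(blocks)
        return D

    def tip_membership(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): tip j is in the subtree at node v."""
        n = self.n_nodes
        M = np.zeros((n, self.n_tips), dtype=bool)
        tip_pos = {int(v): i for i, v in enumerate(self.tips)}
        for v in self.preorder[::-1]:
            if not self.children[v]:
                M[v, tip_pos[int(v)]] = True
            else:
                for c in self.children[v]:
                    M[v] |= M[c]
        return M

    # -- Newick I/O (via dendropy) -------------------------------------------

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                lbl = self.tip_labels[int(np.flatnonzero(self.tips == v)[0])]
            else:
                lbl = ""
            inner = (
                "(" + ",".join(render(c) for c in self.children[v]) + ")"
                if self.children[v]
                else ""
            )
            if v == self.root:
                return f"{inner}{lbl}"
            return f"{inner}{lbl}:{self.lengths[v]:.10g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = []
        lengths = []
        labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(float(nd.edge.length or 0.0))
            if nd.is_leaf():
                name = (
                    nd.taxon.label if nd.taxon is not None else (nd.label or f"t{i}")
                )
                labels[i] = name
        return cls(parent, lengths, labels)


# ---------------------------------------------------------------------------
# Process parameters and the trait-space covariance model


@dataclass(frozen=True)
class ProcessParams:
    """One point in process space.

    ``n`` is the variance of the Gaussian niche function (applied to all
    environmental axes; larger = weaker environmental filtering) and
    ``d`` the variance of the Gaussian dispersal kernel (larger = weaker
    dispersal limitation). Both in squared z-score units.
    """

    n: float
    d: float

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.d > 0):
            raise InvalidArgumentError("process variances n and d must be > 0")


def eq5_covariance(params: ProcessParams, sigma_es_ij: float, D_S: int) -> float:
    """Idealized covariance between trait axis i and space axis j.

    Additive in the two processes: a dispersal term ``exp(-d)`` (1 under
    extreme dispersal limitation, 0 when dispersal is unlimited) plus a
    filtering term ``exp(-n) * sigma_ES`` (filtering can couple traits
    to space only through spatially structured environment), normalized
    by ``2 * D_S`` so covariance summed over dimensions stays in [0, 1].
    """
    if not (0.0 <= sigma_es_ij <= 1.0):
        raise InvalidArgumentError("sigma_es_ij must be in [0, 1]")
    return float(
        (np.exp(-params.d) + np.exp(-params.n) * sigma_es_ij) / (2.0 * D_S)
    )


CovStrategy = Callable[[ProcessParams, float, int], float]


@dataclass(frozen=True)
class TraitSpaceCov:
    """Evolutionary increment covariance over (Trait 1..D_E, Space 1..D_S).

    Unit diagonal; trait-trait and space-space covariances zero;
    trait-space block filled by the covariance model. Must be positive
    semidefinite to drive a Brownian walk.
    """

    matrix: np.ndarray
    D_E: int
    D_S: int

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        k = self.D_E + self.D_S
        if M.shape != (k, k):
            raise InvalidArgumentError("matrix order must equal D_E + D_S")
        if not np.allclose(M, M.T, atol=1e-12):
            raise InvalidArgumentError("covariance matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-12):
            raise InvalidArgumentError("covariance matrix must have unit diagonal")
        tt = M[: self.D_E, : self.D_E]
        ss = M[self.D_E :, self.D_E :]
        if not (
            np.allclose(tt, np.eye(self.D_E), atol=1e-12)
            and np.allclose(ss, np.eye(self.D_S), atol=1e-12)
        ):
            raise InvalidArgumentError(
                "trait-trait and space-space off-diagonals must be zero"
            )
        ts = M[: self.D_E, self.D_E :]
        if np.any(ts < -1e-12) or np.any(ts > 1.0 + 1e-12):
            raise InvalidArgumentError("trait-space covariances must lie in [0, 1]")
        if np.linalg.eigvalsh(M).min() < -1e-10:
            raise ModelInfeasibleError("covariance matrix is not positive semidefinite")
        object.__setattr__(self, "matrix", M)

    @property
    def trait_space_block(self) -> np.ndarray:
        return self.matrix[: self.D_E, self.D_E :]


def build_cov_matrix(
    params: ProcessParams,
    landscape: Landscape,
    cov_fn: CovStrategy = eq5_covariance,
) -> TraitSpaceCov:
    """Assemble the full (D_E + D_S) covariance matrix for a landscape.

    Trait-i x space-j entries come from ``cov_fn`` evaluated at the
    landscape's realized sigma_ES(i, j); all other off-diagonals are
    zero. Raises ``ModelInfeasibleError`` naming the offending
    parameters if the result is not positive semidefinite.
    """
    D_E, D_S = landscape.D_E, landscape.D_S
    if D_E != D_S:
        raise InvalidArgumentError("landscape must have D_E == D_S")
    k = D_E + D_S
    M = np.eye(k)
    for i in range(D_E):
        for j in range(D_S):
            s = float(np.clip(landscape.sigma_ES[i, j], 0.0, 1.0))
            M[i, D_E + j] = M[D_E + j, i] = cov_fn(params, s, D_S)
    try:
        return TraitSpaceCov(matrix=M, D_E=D_E, D_S=D_S)
    except ModelInfeasibleError as exc:
        raise ModelInfeasibleError(
            f"infeasible trait-space covariance at n={params.n!r}, "
            f"d={params.d!r}, sigma_ES={landscape.sigma_ES!r}"
        ) from exc


# ---------------------------------------------------------------------------
# Species pool


@dataclass
class SpeciesPool:
    """Regional pool: phylogeny plus per-species optima, centroids, abundances.

    Rows of ``T`` (species x D_E environmental optima) and ``R``
    (species x D_S range centroids) align with ``phylogeny.tip_labels``.
    ``F`` holds global relative abundances (sum 1) and may be None until
    assigned.
    """

    phylogeny: Phylogeny
    T: np.ndarray
    R: np.ndarray
    F: np.ndarray | None = None
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_ids:
            self.species_ids = list(self.phylogeny.tip_labels)
        n = len(self.species_ids)
        self.T = np.asarray(self.T, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.T.shape[0] != n or self.R.shape[0] != n:
            raise InvalidArgumentError("T and R rows must align with species ids")
        if self.F is not None:
            self.F = np.asarray(self.F, dtype=float)
            if self.F.shape != (n,):
                raise InvalidArgumentError("F must have one entry per species")
            if np.any(self.F <= 0) or not np.isclose(self.F.sum(), 1.0):
                raise InvalidArgumentError("F entries must be positive and sum to 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


# ---------------------------------------------------------------------------
# Birth-death tree simulation


def simulate_tree(
    n_species: int,
    birth: float = 0.1,
    death: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Phylogeny:
    """Grow a birth-death tree until exactly ``n_species`` extant tips.

    Starts from two lineages at the root; waiting times between events
    are exponential with rate ``(birth + death) * k`` for ``k`` live
    lineages, and each event is a speciation with probability
    ``birth / (birth + death)``. After the target richness is reached
    one final waiting time elapses so the youngest pendant branches have
    positive length. Extinct lineages (death > 0) are pruned and
    unifurcations suppressed. With death = 0 the result is an
    ultrametric pure-birth (Yule) tree. Tips are labelled sp1..spN in
    preorder.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    if birth <= 0:
        raise InvalidArgumentError("birth rate must be > 0")
    if death < 0:
        raise InvalidArgumentError("death rate must be >= 0")
    if death >= birth:
        raise InvalidArgumentError(
            "death >= birth: process not guaranteed to reach the target richness"
        )
    rng = np.random.default_rng(seed)
    total = birth + death
    p_birth = birth / total

    while True:  # restart on total extinction
        parent = [-1, 0, 0]
        start = [0.0, 0.0, 0.0]
        end = [0.0, np.nan, np.nan]
        alive = [1, 2]
        t = 0.0
        extinct_all = False
        while len(alive) < n_species:
            k = len(alive)
            t += rng.exponential(1.0 / (total * k))
            idx = int(rng.integers(k))
            v = alive[idx]
            if rng.random() < p_birth:
                end[v] = t
                for _ in range(2):
                    parent.append(v)
                    start.append(t)
                    end.append(np.nan)
                alive[idx] = len(parent) - 2
                alive.append(len(parent) - 1)
            else:
                end[v] = t
                alive.pop(idx)
                if not alive:
                    extinct_all = True
                    break
        if extinct_all:
            continue
        t += rng.exponential(1.0 / (total * n_species))
        for v in alive:
            end[v] = t
        break

    n = len(parent)
    endv = np.asarray(end)
    startv = np.asarray(start)
    is_extant_tip = np.zeros(n, dtype=bool)
    is_extant_tip[alive] = True

    # prune lineages without extant descendants, suppress unifurcations
    keep = is_extant_tip.copy()
    for v in range(n - 1, 0, -1):  # children have larger indices than parents
        if keep[v] and parent[v] >= 0:
            keep[parent[v]] = True
    lengths_full = endv - startv

    new_index = {}
    new_parent: list[int] = []
    new_lengths: list[float] = []

    def effective_parent(v: int) -> tuple[int, float]:
        """Nearest kept ancestor with >= 2 kept children; accumulates length."""
        length = lengths_full[v]
        p = parent[v]
        while p >= 0:
            kept_children = [c for c in range(n) if parent[c] == p and keep[c]]
            if len(kept_children) >= 2:
                return p, length
            length += lengths_full[p]
            p = parent[p]
        return -1, length

    if death == 0.0:
        new_parent = list(parent)
        new_lengths = list(lengths_full)
        node_map = {v: v for v in range(n)}
    else:
        kept_children_count = np.zeros(n, dtype=np.int64)
        for v in range(n):
            if keep[v] and parent[v] >= 0 and keep[parent[v]]:
                kept_children_count[parent[v]] += 1
        structural = [
            v
            for v in range(n)
            if keep[v] and (is_extant_tip[v] or kept_children_count[v] >= 2)
        ]
        # root = first structural node encountered top-down
        node_map = {}
        for v in structural:
            node_map[v] = len(new_parent)
            new_parent.append(-2)  # fill below
            new_lengths.append(0.0)
        for v in structural:
            p, length = effective_parent(v)
            while p >= 0 and p not in node_map:
                p, extra = effective_parent(p)
                length += extra
            new_parent[node_map[v]] = node_map[p] if p >= 0 else -1
            new_lengths[node_map[v]] = length if p >= 0 else 0.0

    tip_nodes = [node_map[v] for v in sorted(alive)]
    labels = {tp: f"sp{i + 1}" for i, tp in enumerate(tip_nodes)}
    return Phylogeny(new_parent, new_lengths, labels)


# ---------------------------------------------------------------------------
# Brownian evolution of traits and range centroids


def evolve_pool(
    tree: Phylogeny,
    cov: TraitSpaceCov,
    seed: int | np.random.Generator = 0,
    standardize: bool = True,
) -> SpeciesPool:
    """Evolve optima and centroids along the tree (returns pool without F).

    A (D_E + D_S)-dimensional Brownian walk runs along every branch with
    increment covariance ``branch_length * cov.matrix`` and root state at
    the origin; tip states split into T (optima) and R (centroids), and
    each column is then standardized to z-scores, matching the model's
    assumption that all axes are standard normal deviates.
    Standardization is monotone, so within-column rank order of tip
    values is preserved; ``standardize=False`` returns the raw Brownian
    tip states (useful for checking increment covariances directly).
    """
    rng = np.random.default_rng(seed)
    k = cov.D_E + cov.D_S
    M = cov.matrix + 1e-10 * np.eye(k)  # PSD jitter for the Cholesky factor
    L = np.linalg.cholesky(M)

    n = tree.n_nodes
    incr = rng.standard_normal((n, k)) @ L.T
    incr *= np.sqrt(np.maximum(tree.lengths, 0.0))[:, None]

    state = np.zeros((n, k))
    for v in tree.preorder:
        p = tree.parent[v]
        if p >= 0:
            state[v] = state[p] + incr[v]

    tip_states = state[tree.tips]
    T = tip_states[:, : cov.D_E]
    R = tip_states[:, cov.D_E :]

    if standardize:

        def zscore(X: np.ndarray) -> np.ndarray:
            sd = X.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            return (X - X.mean(axis=0)) / sd

        T, R = zscore(T), zscore(R)

    return SpeciesPool(phylogeny=tree, T=T, R=R)
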