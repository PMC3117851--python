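import numpy as np
import pytest

from betaproc import (
    Phylogeny,
    ProcessParams,
    TraitSpaceCov,
    build_cov_matrix,
    eq5_covariance,
    evolve_pool,
    generate_landscape,
    simulate_tree,
)
from betaproc.errors import InvalidArgumentError, ModelInfeasibleError


# ---------------------------------------------------------------------------
# Birth-death trees


@pytest.mark.parametrize("n_species", [2, 50, 500])
def test_pure_birth_tree_shape(n_species):
    tree = simulate_tree(n_species, birth=0.1, death=0.0, seed=5)
    assert tree.n_tips == n_species
    assert len(set(tree.tip_labels)) == n_species
    assert tree.is_ultrametric(tol=1e-9)
    # binary tree topology: n - 1 internal nodes
    assert tree.n_nodes == 2 * n_species - 1
    assert np.all(tree.lengths[tree.tips] > 0)


def test_tree_with_extinction_reaches_target_richness():
    tree = simulate_tree(40, birth=0.2, death=0.05, seed=8)
    assert tree.n_tips == 40
    assert len(set(tree.tip_labels)) == 40
    assert np.all(tree.lengths >= 0)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_species=1, birth=0.1, death=0.0),
        dict(n_species=10, birth=0.0, death=0.0),
        dict(n_species=10, birth=0.1, death=0.1),
        dict(n_species=10, birth=0.1, death=0.2),
    ],
)
def test_tree_invalid_arguments(kwargs):
    with pytest.raises(InvalidArgumentError):
        simulate_tree(seed=0, **kwargs)


def test_tree_newick_round_trip():
    tree = simulate_tree(20, 0.1, 0.0, seed=3)
    back = Phylogeny.from_newick(tree.to_newick())
    assert sorted(back.tip_labels) == sorted(tree.tip_labels)
    order = [back.tip_labels.index(l) for l in tree.tip_labels]
    D1 = tree.cophenetic_matrix()
    D2 = back.cophenetic_matrix()[np.ix_(order, order)]
    assert np.allclose(D1, D2, atol=1e-8)


# ---------------------------------------------------------------------------
# Trait-space covariance model


def test_covariance_limits_and_examples():
    # strong/strong with strongly structured environment: ~0.975
    strong = ProcessParams(n=1e-4, d=1e-4)
    assert eq5_covariance(strong, 0.95, 1) == pytest.approx(0.975, abs=1e-3)
    # moderate environmental structure: ~0.65
    assert eq5_covariance(strong, 0.3, 1) == pytest.approx(0.65, abs=1e-3)
    # weak/weak: both contributions e^-10, essentially 0
    weak = ProcessParams(n=10.0, d=10.0)
    assert eq5_covariance(weak, 0.95, 1) < 1e-3


def test_covariance_monotone_decreasing_in_process_breadths():
    grid = [1e-4, 1e-2, 1.0, 10.0]
    vals_n = [eq5_covariance(ProcessParams(n=n, d=0.5), 0.7, 2) for n in grid]
    vals_d = [eq5_covariance(ProcessParams(n=0.5, d=d), 0.7, 2) for d in grid]
    assert np.all(np.diff(vals_n) < 0) and np.all(np.diff(vals_d) < 0)
    assert all(0.0 <= v <= 1.0 for v in vals_n + vals_d)


def test_build_cov_matrix_structure():
    land = generate_landscape(20, 0.7, 2, 2, seed=1)
    cov = build_cov_matrix(ProcessParams(n=1e-4, d=1e-4), land)
    M = cov.matrix
    # paired trait-space entries equal; cross entries are the pure
    # dispersal contribution e^-d / (2 D_S)
    assert M[0, 2] == pytest.approx(M[1, 3])
    assert M[0, 3] == pytest.approx(M[1, 2])
    assert M[0, 3] == pytest.approx(np.exp(-1e-4) / 4.0, abs=1e-9)
    assert M[0, 2] == pytest.approx((np.exp(-1e-4) + np.exp(-1e-4) * 0.7) / 4.0)

    # spatially unstructured environment: all trait-space entries equal
    land0 = generate_landscape(20, 0.0, 2, 2, seed=1)
    cov0 = build_cov_matrix(ProcessParams(n=0.3, d=0.2), land0)
    ts = cov0.trait_space_block
    assert np.allclose(ts, np.exp(-0.2) / 4.0)

    # weak processes: near identity
    covw = build_cov_matrix(ProcessParams(n=10, d=10), land)
    assert np.allclose(covw.matrix, np.eye(4), atol=1e-3)


def test_infeasible_covariance_rejected():
    bad = np.eye(4)
    bad[0, 2] = bad[2, 0] = 0.8
    bad[0, 3] = bad[3, 0] = 0.8
    bad[1, 2] = bad[2, 1] = 0.8
    bad[1, 3] = bad[3, 1] = 0.8
    with pytest.raises(ModelInfeasibleError):
        TraitSpaceCov(matrix=bad, D_E=2, D_S=2)


def test_cov_matrix_validation_errors():
    with pytest.raises(InvalidArgumentError):
        TraitSpaceCov(matrix=np.eye(3), D_E=2, D_S=2)
    M = np.eye(2)
    M[0, 1] = M[1, 0] = -0.5  # negative trait-space covariance
    with pytest.raises(InvalidArgumentError):
        TraitSpaceCov(matrix=M, D_E=1, D_S=1)


# ---------------------------------------------------------------------------
# Brownian evolution


def _two_tip_tree():
    # root with two unit-length branches
    return Phylogeny([-1, 0, 0], [0.0, 1.0, 1.0], {1: "a", 2: "b"})


def test_tip_difference_covariance_is_twice_increment_cov():
    """On a two-tip tree with unit branches the tip difference is the sum
    of two independent unit-time walks, so its covariance is 2 x cov
    (brute-force Monte Carlo, raw tip states)."""
    tree = _two_tip_tree()
    cov = TraitSpaceCov(matrix=np.array([[1.0, 0.6], [0.6, 1.0]]), D_E=1, D_S=1)
    rng = np.random.default_rng(99)
    diffs = np.empty((10_000, 2))
    for i in range(10_000):
        pool = evolve_pool(tree, cov, rng, standardize=False)
        state = np.column_stack([pool.T, pool.R])
        diffs[i] = state[0] - state[1]
    emp = np.cov(diffs.T)
    assert np.allclose(emp, 2.0 * cov.matrix, atol=0.12)


def test_shared_path_covariance_on_cherry_tree():
    """For two tips in the same cherry, state covariance equals shared
    root-to-cherry path length times the increment covariance."""
    # ((a:1,b:1):2,(c:1,d:1):2); shared path for (a,b) = 2
    tree = Phylogeny.from_newick("((a:1,b:1):2,(c:1,d:1):2);")
    cov = TraitSpaceCov(matrix=np.eye(2), D_E=1, D_S=1)
    rng = np.random.default_rng(4)
    prods_same = []
    prods_cross = []
    pos = {l: i for i, l in enumerate(tree.tip_labels)}
    for _ in range(4000):
        pool = evolve_pool(tree, cov, rng, standardize=False)
        t = pool.T[:, 0]
        prods_same.append(t[pos["a"]] * t[pos["b"]])
        prods_cross.append(t[pos["a"]] * t[pos["c"]])
    assert np.mean(prods_same) == pytest.approx(2.0, abs=0.25)
    # disjoint paths -> independent increments -> zero covariance
    assert np.mean(prods_cross) == pytest.approx(0.0, abs=0.2)


def test_identity_cov_gives_uncorrelated_traits_and_centroids():
    cov = TraitSpaceCov(matrix=np.eye(2), D_E=1, D_S=1)
    rng = np.random.default_rng(21)
    cross = []
    # realized per-tree correlations are phylogenetically pseudo-
    # replicated (sd ~ 0.34), so the mean needs a few hundred trees to
    # resolve zero at the 0.05 level
    for rep in range(300):
        tree = simulate_tree(30, 0.1, 0.0, seed=rng)
        pool = evolve_pool(tree, cov, rng)
        cross.append(float(np.mean(pool.T[:, 0] * pool.R[:, 0])))
    assert abs(np.mean(cross)) < 0.05


def test_realized_correlation_tracks_input_covariance():
    """Mean realized Pearson correlation of (T, R) across replicate trees
    approaches the idealized trait-space covariance."""
    entry = 0.975
    cov = TraitSpaceCov(matrix=np.array([[1, entry], [entry, 1.0]]), D_E=1, D_S=1)
    rng = np.random.default_rng(33)
    cors = []
    for rep in range(100):
        tree = simulate_tree(60, 0.1, 0.0, seed=rng)
        pool = evolve_pool(tree, cov, rng)
        cors.append(np.corrcoef(pool.T[:, 0], pool.R[:, 0])[0, 1])
    assert np.mean(cors) == pytest.approx(entry, abs=0.1)


def test_strong_and_weak_process_covariance_regimes():
    """Strong processes with strongly structured environment produce a
    tight trait-centroid relationship; weak processes produce none."""
    rng = np.random.default_rng(55)

    def median_abs_cor(n, d):
        entry = eq5_covariance(ProcessParams(n=n, d=d), 0.95, 1)
        cov = TraitSpaceCov(
            matrix=np.array([[1.0, entry], [entry, 1.0]]), D_E=1, D_S=1
        )
        cors = []
        for _ in range(20):
            # the regional pool's size: shallow-split trees keep the
            # independent-trait correlation spread wide at small n_tips
            tree = simulate_tree(500, 0.1, 0.0, seed=rng)
            pool = evolve_pool(tree, cov, rng)
            cors.append(abs(np.corrcoef(pool.T[:, 0], pool.R[:, 0])[0, 1]))
        return float(np.median(cors))

    assert median_abs_cor(1e-4, 1e-4) > 0.8
    assert median_abs_cor(10.0, 10.0) < 0.2


def test_standardization_preserves_rank_order():
    tree = simulate_tree(40, 0.1, 0.0, seed=2)
    cov = TraitSpaceCov(matrix=np.eye(2), D_E=1, D_S=1)
    raw = evolve_pool(tree, cov, seed=77, standardize=False)
    std = evolve_pool(tree, cov, seed=77, standardize=True)
    assert np.array_equal(np.argsort(raw.T[:, 0]), np.argsort(std.T[:, 0]))
    assert np.allclose(std.T.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(std.T.std(axis=0), 1, atol=1e-12)
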