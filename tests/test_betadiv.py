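import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betaproc import (
    CommunityMatrix,
    DistanceMatrix,
    METRICS,
    Phylogeny,
    all_beta_matrices,
    beta_matrix,
    branch_sorensen,
    bray_curtis,
    cophenetic_distances,
    pairwise_metric_NN,
    pairwise_metric_PW,
    trait_dendrogram,
)
from betaproc.errors import UndefinedMetricError

from conftest import NEWICK5


# ---------------------------------------------------------------------------
# Cophenetic distances


def _brute_force_cophenetic(tree: Phylogeny) -> np.ndarray:
    """Independent path-sum oracle: climb both tips to their first shared
    ancestor, adding branch lengths."""
    n = tree.n_tips
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            va, vb = int(tree.tips[a]), int(tree.tips[b])
            anc_a = {}
            v, dist = va, 0.0
            while v != -1:
                anc_a[v] = dist
                dist += tree.lengths[v]
                v = int(tree.parent[v])
            v, dist = vb, 0.0
            while v not in anc_a:
                dist += tree.lengths[v]
                v = int(tree.parent[v])
            D[a, b] = D[b, a] = dist + anc_a[v]
    return D


def test_cophenetic_trivial_cases():
    two = Phylogeny.from_newick("(a:1,b:1);")
    D = cophenetic_distances(two)
    assert D.matrix[0, 1] == pytest.approx(2.0)
    cherry = Phylogeny.from_newick("((a:1,b:1):3,(c:1,d:1):3);")
    M = cophenetic_distances(cherry).matrix
    pos = {l: i for i, l in enumerate(cherry.tip_labels)}
    assert M[pos["a"], pos["b"]] == M[pos["c"], pos["d"]] == pytest.approx(2.0)


def test_cophenetic_matches_path_sum_oracle(tree5):
    assert np.allclose(tree5.cophenetic_matrix(), _brute_force_cophenetic(tree5))


def test_cophenetic_matches_fixture_oracle(tree5, expected_values):
    D = cophenetic_distances(tree5)
    pos = {l: i for i, l in enumerate(D.ids)}
    for key, val in expected_values["cophenetic_tree5"].items():
        a, b = key.split("|")
        assert D.matrix[pos[a], pos[b]] == pytest.approx(val)


# ---------------------------------------------------------------------------
# Trait dendrogram (UPGMA)


def test_upgma_two_species():
    dend = trait_dendrogram(np.array([[0.0], [2.0]]), ["a", "b"])
    assert np.all(np.isclose(dend.lengths[dend.tips], 1.0))
    assert dend.cophenetic_matrix()[0, 1] == pytest.approx(2.0)


def test_upgma_first_merge_joins_nearest_pair():
    dend = trait_dendrogram(np.array([[0.0], [1.0], [10.0]]), ["a", "b", "c"])
    M = dend.cophenetic_matrix()
    pos = {l: i for i, l in enumerate(dend.tip_labels)}
    assert M[pos["a"], pos["b"]] < M[pos["a"], pos["c"]]
    assert M[pos["a"], pos["b"]] == pytest.approx(1.0)


def test_upgma_matches_hand_run_merge_table(fixture_dir, expected_values):
    """Dendrogram cophenetic distances equal those implied by a naive
    hand-executed UPGMA on the 6-species fixture traits."""
    import pandas as pd

    df = pd.read_csv(fixture_dir / "traits6.csv")
    traits = df[["trait1"]].to_numpy()
    ids = list(df["species_id"])
    dend = trait_dendrogram(traits, ids)
    M = dend.cophenetic_matrix()
    pos = {l: i for i, l in enumerate(dend.tip_labels)}

    # replay oracle merges to derive every pairwise cophenetic height
    members = {i: [ids[i]] for i in range(6)}
    for merge in expected_values["upgma_merges_traits6"]:
        a, b = merge["join"]
        for x in members[a]:
            for y in members[b]:
                assert M[pos[x], pos[y]] == pytest.approx(merge["height"], abs=1e-9)
        members[merge["new"]] = members.pop(a) + members.pop(b)


# ---------------------------------------------------------------------------
# Pairwise PW / NN arithmetic oracles


DELTA = np.array([[0.0, 2.0, 5.0], [2.0, 0.0, 3.0], [5.0, 3.0, 0.0]])


def test_pw_matches_four_term_hand_sum():
    p_k = np.array([0.5, 0.5, 0.0])
    p_l = np.array([0.0, 0.5, 0.5])
    # by hand: .5*.5*d12 + .5*.5*d13 + .5*.5*d22 + .5*.5*d23
    expected = 0.25 * (2.0 + 5.0 + 0.0 + 3.0)
    assert pairwise_metric_PW(p_k, p_l, DELTA) == pytest.approx(expected)


def test_pw_trivial_and_self_comparison():
    a = np.array([1.0, 0.0, 0.0])
    b = np.array([0.0, 1.0, 0.0])
    assert pairwise_metric_PW(a, b, DELTA) == pytest.approx(2.0)
    assert pairwise_metric_PW(b, b, DELTA) == pytest.approx(0.0)
    # PW of a mixed community with itself is its within-community mean
    # pairwise distance, NOT zero
    mixed = np.array([0.5, 0.5, 0.0])
    assert pairwise_metric_PW(mixed, mixed, DELTA) == pytest.approx(1.0)


def test_nn_matches_hand_computed_minimum_sums():
    p_k = np.array([0.5, 0.5, 0.0])
    p_l = np.array([0.0, 0.5, 0.5])
    # species 1 -> min(d12, d13) = 2 ; species 2 -> 0 (itself in l)
    # species 2 in l -> 0 ; species 3 -> min(d31, d32) = 3
    expected = 0.5 * (0.5 * 2.0 + 0.5 * 0.0) + 0.5 * (0.5 * 0.0 + 0.5 * 3.0)
    assert pairwise_metric_NN(p_k, p_l, DELTA) == pytest.approx(expected)


def test_nn_identity_and_singletons():
    a = np.array([1.0, 0.0, 0.0])
    b = np.array([0.0, 1.0, 0.0])
    mixed = np.array([0.3, 0.7, 0.0])
    assert pairwise_metric_NN(a, b, DELTA) == pytest.approx(2.0)
    assert pairwise_metric_NN(mixed, mixed, DELTA) == pytest.approx(0.0)


def test_empty_community_is_undefined():
    with pytest.raises(UndefinedMetricError):
        pairwise_metric_PW(np.zeros(3), np.array([1.0, 0, 0]), DELTA)
    with pytest.raises(UndefinedMetricError):
        pairwise_metric_NN(np.array([1.0, 0, 0]), np.zeros(3), DELTA)


# ---------------------------------------------------------------------------
# Branch-length Sorensen


def _edge_marking_sorensen(tree: Phylogeny, set_k: set, set_l: set) -> float:
    """Independent oracle: mark every edge as belonging to the spanning
    subtree of k, of l, or both, by brute-force tip enumeration."""
    M = tree.tip_membership()
    labels = np.array(tree.tip_labels)
    B = {"k": 0.0, "l": 0.0, "kl": 0.0}
    for v in range(tree.n_nodes):
        below = set(labels[M[v]])
        in_k = bool(below & set_k) and bool(set_k - below)
        in_l = bool(below & set_l) and bool(set_l - below)
        if in_k:
            B["k"] += tree.lengths[v]
        if in_l:
            B["l"] += tree.lengths[v]
        if in_k and in_l:
            B["kl"] += tree.lengths[v]
    if B["k"] + B["l"] == 0:
        return 1.0 if set_k == set_l else 0.0
    return 2 * B["kl"] / (B["k"] + B["l"])


def test_branch_sorensen_identity_and_disjoint_cherries():
    tree = Phylogeny.from_newick("((a:1,b:1):2,(c:1,d:1):2);")
    assert branch_sorensen(tree, {"a", "b"}, {"a", "b"}) == pytest.approx(1.0)
    assert branch_sorensen(tree, {"a", "b"}, {"c", "d"}) == pytest.approx(0.0)


@pytest.mark.parametrize(
    "set_k,set_l",
    [
        ({"t1", "t3"}, {"t3", "t4", "t5"}),
        ({"t1", "t2", "t4"}, {"t2", "t4"}),
        ({"t1", "t2", "t3", "t4", "t5"}, {"t4", "t5"}),
        ({"t1"}, {"t2"}),
    ],
)
def test_branch_sorensen_matches_edge_marking_oracle(tree5, set_k, set_l):
    got = branch_sorensen(tree5, set_k, set_l)
    assert got == pytest.approx(_edge_marking_sorensen(tree5, set_k, set_l))


def test_branch_sorensen_empty_community_undefined(tree5):
    with pytest.raises(UndefinedMetricError):
        branch_sorensen(tree5, set(), {"t1"})


# ---------------------------------------------------------------------------
# Bray-Curtis and the Sorensen collapse


def test_bray_curtis_identities():
    a = np.array([0.2, 0.3, 0.5, 0.0])
    assert bray_curtis(a, a) == pytest.approx(0.0)
    disjoint = np.array([0.0, 0.0, 0.0, 1.0])
    other = np.array([0.5, 0.5, 0.0, 0.0])
    assert bray_curtis(disjoint, other) == pytest.approx(1.0)
    assert 0.0 <= bray_curtis(a, other) <= 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**10 - 1),
       st.integers(min_value=0, max_value=2**10 - 1))
def test_bray_curtis_collapses_to_one_minus_sorensen(bits_k, bits_l):
    """With presence/absence relative abundances, BC equals 1 minus the
    taxonomic Sorensen similarity, exactly."""
    pres_k = np.array([(bits_k >> i) & 1 for i in range(10)], dtype=float)
    pres_l = np.array([(bits_l >> i) & 1 for i in range(10)], dtype=float)
    if pres_k.sum() == 0 or pres_l.sum() == 0:
        return
    a = float((pres_k * pres_l).sum())
    sor = 2 * a / (pres_k.sum() + pres_l.sum())
    assert bray_curtis(pres_k, pres_l) == pytest.approx(1.0 - sor, abs=1e-12)


# ---------------------------------------------------------------------------
# Full beta matrices


def _toy_community(tree5):
    counts = np.array(
        [[5, 5, 0, 0, 0], [0, 4, 4, 2, 0], [0, 0, 2, 4, 4], [3, 0, 0, 3, 4]]
    )
    return CommunityMatrix(
        counts=counts,
        site_ids=[f"site{i+1}" for i in range(4)],
        species_ids=["t1", "t2", "t3", "t4", "t5"],
        J=10,
    )


@pytest.mark.parametrize("metric", METRICS)
def test_beta_matrix_shape_symmetry_and_identity(tree5, metric):
    comm = _toy_community(tree5)
    traits = np.array([[0.0, 1.0], [0.2, 0.8], [1.0, 0.0], [1.1, 0.2], [0.9, -0.1]])
    bm = beta_matrix(metric, comm, tree=tree5, traits=traits)
    V = bm.values
    assert V.shape == (4, 4)
    assert np.allclose(V, V.T)
    assert len(bm.condensed()) == 4 * 3 // 2
    if metric in ("BC", "tax_SOR", "phy_SOR", "fun_SOR"):
        assert np.all((V >= -1e-12) & (V <= 1 + 1e-12))
    else:
        assert np.all(V >= -1e-12)

    # duplicated site: metric takes its identity value
    dup = CommunityMatrix(
        counts=np.vstack([comm.counts[:1], comm.counts[:1]]),
        site_ids=["x", "y"],
        species_ids=comm.species_ids,
        J=10,
    )
    bm2 = beta_matrix(metric, dup, tree=tree5, traits=traits)
    ident = 1.0 if bm.orientation == "similarity" else 0.0
    if metric in ("phy_PW", "fun_PW"):
        assert bm2.values[0, 1] == pytest.approx(bm2.values[0, 0])
    else:
        assert bm2.values[0, 1] == pytest.approx(ident, abs=1e-9)


@pytest.mark.parametrize("metric", METRICS)
def test_beta_matrix_invariant_to_species_permutation(tree5, metric, rng):
    comm = _toy_community(tree5)
    traits = rng.normal(size=(5, 2))
    ref = beta_matrix(metric, comm, tree=tree5, traits=traits).values
    perm = rng.permutation(5)
    comm_p = CommunityMatrix(
        counts=comm.counts[:, perm],
        site_ids=comm.site_ids,
        species_ids=[comm.species_ids[j] for j in perm],
        J=10,
    )
    got = beta_matrix(metric, comm_p, tree=tree5, traits=traits[perm]).values
    assert np.allclose(ref, got, atol=1e-9)


def test_all_beta_matrices_matches_single_metric_path(tree5, rng):
    comm = _toy_community(tree5)
    traits = rng.normal(size=(5, 2))
    combined = all_beta_matrices(comm, tree=tree5, traits=traits)
    assert set(combined) == set(METRICS)
    for metric in METRICS:
        single = beta_matrix(metric, comm, tree=tree5, traits=traits)
        assert np.allclose(combined[metric].values, single.values, atol=1e-9)
        assert combined[metric].orientation == single.orientation


def test_functional_distance_source_switch(tree5, rng):
    """Dendrogram-based and direct-trait functional PW disagree in
    general; an explicit distance matrix takes precedence."""
    comm = _toy_community(tree5)
    traits = rng.normal(size=(5, 2))
    via_dend = beta_matrix("fun_PW", comm, traits=traits).values
    via_traits = beta_matrix(
        "fun_PW", comm, traits=traits, functional_distance="traits"
    ).values
    assert not np.allclose(via_dend, via_traits)
    from scipy.spatial.distance import pdist, squareform

    explicit = DistanceMatrix(squareform(pdist(traits)), list(comm.species_ids))
    via_dist = beta_matrix("fun_PW", comm, dist=explicit).values
    assert np.allclose(via_dist, via_traits)
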