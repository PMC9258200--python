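"""Walk sampling and the three embedding backends."""

import numpy as np
import pytest

import varmodnet as vm
from varmodnet.network import AssociationMatrix


def _block_ajm(sizes, within=2.0, across=-2.0):
    n = sum(sizes)
    loa = np.full((n, n), across)
    start = 0
    for s in sizes:
        loa[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(loa, 0.0)
    return AssociationMatrix("G", [f"v{i}" for i in range(n)], loa)


def test_sample_walks_counts_and_length():
    ajm = _block_ajm([3])
    corpus = vm.sample_walks(ajm, walks_per_node=10, walk_length=10, seed=0)
    assert len(corpus.walks) == 30
    assert all(len(w) == 10 for w in corpus.walks)


def test_sample_walks_two_nodes_alternate():
    ajm = _block_ajm([2])
    corpus = vm.sample_walks(ajm, seed=1)
    for walk in corpus.walks:
        assert all(walk[i] != walk[i + 1] for i in range(len(walk) - 1))


def test_sample_walks_softmax_step_probabilities():
    """Neighbors at LOA 0 and LOA ln 3 are chosen with odds 1:3."""
    loa = np.array([[0.0, 0.0, np.log(3)], [0.0, 0.0, 0.0], [np.log(3), 0.0, 0.0]])
    ajm = AssociationMatrix("G", ["s", "a", "b"], loa)
    corpus = vm.sample_walks(ajm, walks_per_node=400, walk_length=2, seed=5)
    steps = [w[1] for w in corpus.walks if w[0] == "s"]
    frac_b = np.mean([s == "b" for s in steps])
    # 400 Bernoulli(0.75) draws: 4 sigma ~ 0.087
    assert frac_b == pytest.approx(0.75, abs=0.09)


def test_sample_walks_deterministic():
    ajm = _block_ajm([3, 3])
    w1 = vm.sample_walks(ajm, seed=9).walks
    w2 = vm.sample_walks(ajm, seed=9).walks
    assert w1 == w2


def test_skipgram_separates_two_cliques():
    ajm = _block_ajm([3, 3])
    corpus = vm.sample_walks(ajm, seed=2)
    table = vm.embed_skipgram(corpus, seed=2)
    X = table.matrix([f"v{i}" for i in range(6)])
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    cos = Xn @ Xn.T
    within = (cos[:3, :3][np.triu_indices(3, 1)].mean() + cos[3:, 3:][np.triu_indices(3, 1)].mean()) / 2
    across = cos[:3, 3:].mean()
    assert within > across + 0.3


def test_skipgram_total_and_deterministic():
    ajm = _block_ajm([2])
    corpus = vm.sample_walks(ajm, seed=3)
    t1 = vm.embed_skipgram(corpus, seed=3)
    t2 = vm.embed_skipgram(corpus, seed=3)
    assert set(t1.vectors) == {"v0", "v1"}
    for v in t1.vectors:
        assert np.isfinite(t1.vectors[v]).all()
        assert np.array_equal(t1.vectors[v], t2.vectors[v])


def test_pca_degenerate_zero_matrix():
    ajm = AssociationMatrix("G", ["a", "b", "c"], np.zeros((3, 3)))
    table = vm.embed_pca(ajm, dim=2)
    vecs = list(table.vectors.values())
    assert all(np.allclose(v, vecs[0]) for v in vecs)


def _eig_scores(loa, comp_idx):
    """Independent oracle: PCA scores via eigendecomposition of X'X."""
    X = loa - loa.mean(axis=0)
    evals, evecs = np.linalg.eigh(X.T @ X)
    w = evecs[:, np.argsort(evals)[::-1][comp_idx]]
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return X @ w


def test_pca_matches_eigendecomposition_on_block_fixture():
    """On a two-block matrix PC1 is unique (asymmetric blocks): it matches an
    independent eigendecomposition and separates the blocks."""
    n = 6
    loa = np.full((n, n), -1.0)
    loa[:4, :4] = 2.0
    loa[4:, 4:] = 1.2
    np.fill_diagonal(loa, 0.0)
    ajm = AssociationMatrix("G", [f"v{i}" for i in range(n)], loa)
    table = vm.embed_pca(ajm, dim=2)
    pc1 = table.matrix(ajm.variant_order)[:, 0]
    assert np.allclose(pc1, _eig_scores(loa, 0), atol=1e-8)
    assert max(pc1[4:]) < min(pc1[:4]) or min(pc1[4:]) > max(pc1[:4])


def test_pca_matches_eigendecomposition_generic_matrix():
    """Full score comparison on a generic symmetric matrix (distinct spectrum)."""
    rng = np.random.default_rng(6)
    raw = rng.normal(size=(6, 6))
    loa = np.triu(raw, 1) + np.triu(raw, 1).T
    ajm = AssociationMatrix("G", [f"v{i}" for i in range(6)], loa)
    got = vm.embed_pca(ajm, dim=3).matrix(ajm.variant_order)
    for comp_idx in range(3):
        assert np.allclose(got[:, comp_idx], _eig_scores(loa, comp_idx), atol=1e-8)


def test_pca_component_variance_ordering():
    rng = np.random.default_rng(0)
    raw = rng.normal(size=(6, 6))
    loa = np.triu(raw, 1) + np.triu(raw, 1).T
    table = vm.embed_pca(AssociationMatrix("G", [f"v{i}" for i in range(6)], loa), dim=3)
    X = table.matrix([f"v{i}" for i in range(6)])
    variances = X.var(axis=0)
    assert variances[0] >= variances[1] >= variances[2]


def test_pca_pads_small_genes():
    ajm = _block_ajm([2])
    table = vm.embed_pca(ajm, dim=2)
    X = table.matrix(["v0", "v1"])
    assert X.shape == (2, 2)
    assert np.allclose(X[:, 1], 0.0)  # padded component


def test_nmf_nonnegative_and_rank1():
    ajm = AssociationMatrix("G", ["a", "b", "c"], np.zeros((3, 3)))
    table = vm.embed_nmf(ajm, dim=1)
    W = table.matrix(["a", "b", "c"])
    assert (W >= 0).all()
    # AJNM of the zero matrix is all-ones (rank 1): near-exact reconstruction
    approx = np.outer(W[:, 0], W[:, 0]) / np.linalg.norm(W[:, 0]) ** 2 * W.sum()
    assert np.isfinite(approx).all()


def test_nmf_deterministic_and_separates_blocks():
    ajm = _block_ajm([3, 3], within=1.2, across=-1.2)
    t1 = vm.embed_nmf(ajm, dim=2)
    t2 = vm.embed_nmf(ajm, dim=2)
    for v in t1.vectors:
        assert np.array_equal(t1.vectors[v], t2.vectors[v])
        assert (t1.vectors[v] >= 0).all()
    cands = vm.cluster_embeddings(t1)
    groups = {frozenset(c.variants) for c in cands}
    assert groups == {frozenset({"v0", "v1", "v2"}), frozenset({"v3", "v4", "v5"})}


@pytest.mark.parametrize("backend", ["gmf_pca", "gmf_nmf"])
def test_gmf_permutation_equivariance(backend):
    rng = np.random.default_rng(4)
    raw = rng.normal(scale=0.8, size=(7, 7))
    loa = np.triu(raw, 1) + np.triu(raw, 1).T
    names = [f"v{i}" for i in range(7)]
    ajm = AssociationMatrix("G", names, loa)
    perm = rng.permutation(7)
    ajm_p = AssociationMatrix("G", [names[i] for i in perm], loa[np.ix_(perm, perm)])
    t = vm.embed(ajm, backend)
    t_p = vm.embed(ajm_p, backend)
    for v in names:
        assert np.allclose(t.vectors[v], t_p.vectors[v], atol=1e-6)


def test_all_backends_finite_and_deterministic(toy_cohort):
    ajm = vm.build_ajm("G", toy_cohort.variants, toy_cohort)
    for backend in vm.BACKENDS:
        a = vm.embed(ajm, backend, seed=11)
        b = vm.embed(ajm, backend, seed=11)
        for v in a.vectors:
            assert np.isfinite(a.vectors[v]).all()
            assert np.array_equal(a.vectors[v], b.vectors[v])
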