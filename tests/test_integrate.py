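"""kNN graph, modularity clustering, tSNE, supervised labels and CCA alignment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from ctcdetect.integrate import (
    _quantile_map,
    knn_graph,
    modularity_cluster,
    run_cca,
    supervised_label,
    tsne_embed,
    union_top_dispersion,
)
from ctcdetect.io import DataError
from ctcdetect.preprocess import lognormalize


def _blobs(rng, n_per, centers, scale=1.0):
    pts = [rng.normal(c, scale, size=(n_per, len(c))) for c in centers]
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# kNN graph


def test_three_equidistant_points_form_cycle():
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    g = knn_graph(tri, k=1)
    assert g.ecount() == 3 and g.is_connected()


def test_separated_blobs_have_no_cross_edges():
    rng = np.random.default_rng(0)
    X = _blobs(rng, 50, [np.zeros(3), np.full(3, 20.0)])  # 20 sigma apart
    g = knn_graph(X, k=10)
    for e in g.es:
        assert (e.source < 50) == (e.target < 50)


def test_neighbors_match_bruteforce_sort():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(100, 4))
    k = 7
    g = knn_graph(X, k=k)
    edges = {tuple(sorted((e.source, e.target))) for e in g.es}
    # brute force: all-pairs distances, union-symmetrized k nearest
    D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    np.fill_diagonal(D, np.inf)
    expect = set()
    for i in range(100):
        order = np.argsort(D[i])[:k]
        for j in order:
            expect.add(tuple(sorted((i, int(j)))))
    assert edges == expect


def test_k_must_be_smaller_than_n():
    with pytest.raises(ValueError):
        knn_graph(np.zeros((5, 2)), k=5)


# ---------------------------------------------------------------------------
# Modularity clustering


def test_two_cliques_give_two_clusters():
    import igraph as ig

    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i + 5, j + 5) for i, j in edges[: len(edges)]]
    g = ig.Graph(n=10, edges=edges)
    g.es["weight"] = 1.0
    labels = modularity_cluster(g, resolution=0.8, seed=0)
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_achieved_modularity_beats_truth_partition(small_dataset):
    cm, truth = small_dataset
    rng = np.random.default_rng(2)
    pops = truth.table.population.to_numpy()
    centers = {p: i for i, p in enumerate(pd.unique(pops))}
    emb = np.array([[centers[p] * 6.0, 0.0] for p in pops]) + rng.normal(
        size=(len(pops), 2)
    )
    g = knn_graph(emb, k=15)
    labels = modularity_cluster(g, resolution=0.8, seed=0)
    truth_membership = [centers[p] for p in pops]
    q_achieved = g.modularity(list(labels), weights="weight")
    q_truth = g.modularity(truth_membership, weights="weight")
    assert q_achieved >= q_truth - 0.02


def test_clustering_invariant_to_barcode_order():
    """With named vertices the partition depends only on the cells, not on
    the order they arrived in."""
    rng = np.random.default_rng(3)
    X = _blobs(rng, 60, [np.zeros(2), np.full(2, 15.0), np.array([15.0, -15.0])])
    names = [f"B{i:03d}" for i in range(len(X))]
    base = modularity_cluster(knn_graph(X, k=8, names=names), resolution=0.8, seed=4)
    perm = rng.permutation(len(X))
    shuffled = modularity_cluster(
        knn_graph(X[perm], k=8, names=[names[i] for i in perm]),
        resolution=0.8, seed=4,
    )
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(base, shuffled[inv]) == 1.0


# ---------------------------------------------------------------------------
# tSNE


def test_tsne_deterministic_given_seed():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 5))
    a = tsne_embed(X, perplexity=10, seed=1)
    b = tsne_embed(X, perplexity=10, seed=1)
    assert np.array_equal(a, b)


def test_tsne_rejects_tiny_input():
    with pytest.raises(DataError, match="perplexity"):
        tsne_embed(np.zeros((2, 3)), perplexity=30)


def test_tsne_separates_distant_blobs():
    rng = np.random.default_rng(6)
    X = _blobs(rng, 50, [np.zeros(5), np.full(5, 20.0)])
    coords = tsne_embed(X, perplexity=15, seed=0)
    labels = np.array([0] * 50 + [1] * 50)
    assert silhouette_score(coords, labels) > 0.5


# ---------------------------------------------------------------------------
# Supervised labels


def test_supervised_label_identity_without_flags():
    clusters = pd.DataFrame({"barcode": ["a", "b"], "cluster": [0, 1]})
    calls = pd.DataFrame({"barcode": ["a", "b"], "flagged": [False, False]})
    out = supervised_label(clusters, calls)
    assert list(out.label) == ["0", "1"]


def test_supervised_label_overrides_cluster():
    clusters = pd.DataFrame({"barcode": list("abcde"), "cluster": [0] * 5})
    calls = pd.DataFrame(
        {"barcode": list("abcde"), "flagged": [True, False, True, True, False]}
    )
    out = supervised_label(clusters, calls)
    assert (out.label == "CTC").sum() == 3
    assert set(out.loc[out.label == "CTC", "barcode"]) == {"a", "c", "d"}


def test_supervised_label_reinserts_missing_flagged():
    clusters = pd.DataFrame({"barcode": ["a", "b"], "cluster": [0, 1]})
    calls = pd.DataFrame({"barcode": ["a", "b", "z"], "flagged": [False, True, True]})
    with pytest.warns(UserWarning, match="re-inserted"):
        out = supervised_label(clusters, calls)
    assert set(out.loc[out.label == "CTC", "barcode"]) == {"b", "z"}
    assert len(out) == 3


# ---------------------------------------------------------------------------
# Dispersion union


def test_union_identical_datasets_is_n_top():
    rng = np.random.default_rng(7)
    X = rng.poisson(2.0, size=(50, 30)).astype(float)
    ln = np.log1p(X)
    genes = [f"g{i}" for i in range(50)]
    union = union_top_dispersion(ln, genes, ln, genes, n_top=10)
    assert len(union) == 10


def test_union_disjoint_tops_is_two_n_top():
    ln1 = np.zeros((20, 40))
    ln2 = np.zeros((20, 40))
    rng = np.random.default_rng(8)
    # high-dispersion genes 0-4 in dataset 1, 10-14 in dataset 2
    ln1[:5, :4] = np.log1p(rng.poisson(50.0, size=(5, 4)))
    ln1[5:, :] = np.log1p(1.0)
    ln2[10:15, :4] = np.log1p(rng.poisson(50.0, size=(5, 4)))
    ln2[:10, :] = np.log1p(1.0)
    ln2[15:, :] = np.log1p(1.0)
    genes = [f"g{i}" for i in range(20)]
    union = union_top_dispersion(ln1, genes, ln2, genes, n_top=5)
    assert len(union) == 10


def test_union_matches_bruteforce(small_dataset):
    cm, _ = small_dataset
    ln = lognormalize(cm)
    genes = cm.gene_symbols
    union = union_top_dispersion(ln, genes, ln, genes, n_top=100)
    X = np.expm1(ln.toarray())
    disp = np.where(
        X.mean(axis=1) > 0, X.var(axis=1, ddof=1) / np.maximum(X.mean(axis=1), 1e-300), 0
    )
    expect = [genes[i] for i in np.argsort(-disp, kind="stable")[:100]]
    assert set(union) == set(expect)


# ---------------------------------------------------------------------------
# CCA


def test_cca_self_similarity():
    rng = np.random.default_rng(9)
    ln = np.log1p(rng.poisson(3.0, size=(60, 80)).astype(float))
    genes = [f"g{i}" for i in range(60)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = run_cca(ln, genes, ln, genes, genes[:50], n_cv=5)
    assert model.canonical_correlations[0] == pytest.approx(1.0, abs=1e-8)
    assert model.aligned_embeddings_2 == pytest.approx(
        model.cv_embeddings_1, abs=1e-6
    )


def test_cca_independent_data_below_permutation_null():
    rng = np.random.default_rng(10)
    genes = [f"g{i}" for i in range(60)]
    ln1 = np.log1p(rng.poisson(3.0, size=(60, 80)).astype(float))
    ln2 = np.log1p(rng.poisson(3.0, size=(60, 70)).astype(float))

    def leading_cc(a, b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_cca(a, genes, b, genes, genes, n_cv=3).canonical_correlations[0]

    observed = leading_cc(ln1, ln2)
    null = []
    for _ in range(49):
        perm = rng.permutation(60)
        null.append(leading_cc(ln1, ln2[perm][np.argsort(perm)][rng.permutation(60)]))
    assert observed <= np.quantile(null, 0.95) + 0.05


def test_cca_alignment_shrinks_population_centroids():
    from ctcdetect.sim import SimConfig, generate_dataset

    cm1, t1 = generate_dataset(SimConfig(n_cells=500, n_rare=1, seed=21))
    cm2, t2 = generate_dataset(
        SimConfig(n_cells=400, n_rare=1, seed=22, libsize_lognormal_params=(7.9, 0.5))
    )
    ln1, ln2 = lognormalize(cm1), lognormalize(cm2)
    genes = union_top_dispersion(
        ln1, cm1.gene_symbols, ln2, cm2.gene_symbols, n_top=800
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = run_cca(ln1, cm1.gene_symbols, ln2, cm2.gene_symbols, genes, n_cv=10)
    pops1 = t1.table.set_index("barcode").population
    pops2 = t2.table.set_index("barcode").population
    shrunk = 0
    tested = 0
    for pop in ["T", "B", "NK", "monocyte", "RBC"]:
        m1 = (pops1.loc[cm1.barcodes] == pop).to_numpy()
        m2 = (pops2.loc[cm2.barcodes] == pop).to_numpy()
        c1 = model.cv_embeddings_1[m1].mean(axis=0)
        pre = np.linalg.norm(c1 - model.cv_embeddings_2[m2].mean(axis=0))
        post = np.linalg.norm(c1 - model.aligned_embeddings_2[m2].mean(axis=0))
        tested += 1
        shrunk += post < pre
    # at this reduced size one marginal population may not shrink; the
    # study-size check (every population shrinks) lives in the acceptance
    # suite
    assert tested == 5 and shrunk >= 4


def test_quantile_map_is_monotone_and_order_preserving():
    rng = np.random.default_rng(11)
    ref = rng.normal(size=200)
    vals = rng.normal(2.0, 3.0, size=150)
    mapped = _quantile_map(ref, vals)
    order = np.argsort(vals)
    assert (np.diff(mapped[order]) >= 0).all()
    assert mapped.shape == vals.shape


def test_cca_missing_genes_rejected():
    ln = np.zeros((3, 4))
    with pytest.raises(DataError, match="absent"):
        run_cca(ln, ["a", "b", "c"], ln, ["a", "b", "x"], ["a", "c"], n_cv=2)
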