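"""The robust blood-compartment analysis and two-sample integration.

Non-outlier blood cells are clustered on PC space with a shared-neighbor
kNN graph and seeded modularity optimization, visualized with tSNE, and the
candidate tumor cells found by the outlier pass are written back in as a
supervised "CTC" label.  Two patients' datasets are combined by taking the
union of their top-dispersion genes, computing 20 canonical vectors via an
SVD of the cross-product of the gene-standardized matrices, and aligning
the per-component embedding distributions with a monotone quantile map to
remove batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .io import DataError
from .preprocess import scale_genes

CTC_LABEL = "CTC"


# ---------------------------------------------------------------------------
# Graph clustering


def knn_graph(
    embeddings: np.ndarray, k: int = 30, names: list[str] | None = None
) -> ig.Graph:
    """Union-symmetrized kNN graph in PC space with Jaccard edge weights.

    Neighbors tied with the k-th smallest distance are all included, so
    exactly-equidistant geometries resolve symmetrically; edge weights are
    the shared-neighbor (Jaccard) overlap of the two endpoint neighbor sets.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    # fetch extra neighbors so boundary ties can be detected and included
    n_fetch = min(n - 1, k + 8)
    nn = NearestNeighbors(n_neighbors=n_fetch + 1).fit(X)
    dist, ind = nn.kneighbors(X)
    neigh_sets: list[set[int]] = []
    for i in range(n):
        d, j = dist[i], ind[i]
        keep = j != i
        d, j = d[keep][:n_fetch], j[keep][:n_fetch]
        kth = d[k - 1]
        members = j[d <= kth + 1e-12]
        neigh_sets.append(set(int(x) for x in members))
    edges, weights = [], []
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        for j in neigh_sets[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh_sets[a] & neigh_sets[b])
            union = len(neigh_sets[a] | neigh_sets[b])
            edges.append((a, b))
            weights.append(inter / union if union else 0.0)
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    g.simplify(combine_edges="first")
    if names is not None:
        if len(names) != n:
            raise ValueError("names length must match the number of cells")
        g.vs["name"] = list(names)
    return g


def modularity_cluster(graph: ig.Graph, resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Seeded greedy modularity optimization (Leiden, RB-configuration).

    Deterministic given the seed; disconnected graphs cluster per component
    and singleton communities are permitted.  Greedy optimization is
    sensitive to vertex order, so when vertices carry names (barcodes) the
    graph is canonicalized by name first — the result then depends only on
    the cells, not on the order they arrived in.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    inverse = None
    if "name" in graph.vertex_attributes():
        names = graph.vs["name"]
        rank = {v: i for i, v in enumerate(sorted(names))}
        perm = [rank[v] for v in names]  # new id of each old vertex
        graph = graph.permute_vertices(perm)
        inverse = np.asarray(perm)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.edge_attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.asarray(part.membership)
    return membership[inverse] if inverse is not None else membership


def tsne_embed(pc_embeddings: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D tSNE of the PC coordinates — visualization only, never used for calling."""
    X = np.asarray(pc_embeddings, dtype=np.float64)
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise DataError(
            f"perplexity={perplexity} too large for {n} cells; "
            f"choose perplexity < {(n - 1) / 3:.1f}"
        )
    model = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return model.fit_transform(X)


def supervised_label(clusters: pd.DataFrame, outlier_calls: pd.DataFrame) -> pd.DataFrame:
    """Overwrite graph-cluster labels of flagged outliers with "CTC".

    ``clusters`` needs columns barcode, cluster.  Flagged barcodes missing
    from the clustering (e.g. filtered out) are re-inserted with a warning.
    """
    out = clusters.copy()
    out["label"] = out["cluster"].astype(str)
    flagged = list(outlier_calls.loc[outlier_calls["flagged"], "barcode"])
    present = set(out["barcode"])
    out.loc[out["barcode"].isin(flagged), "label"] = CTC_LABEL
    missing = [b for b in flagged if b not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} flagged barcodes absent from clustering; re-inserted as CTC"
        )
        add = pd.DataFrame(
            {"barcode": missing, "cluster": pd.NA, "label": CTC_LABEL}
        )
        out = pd.concat([out, add], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Two-dataset integration


def _dispersion(lognorm) -> np.ndarray:
    X = lognorm.tocsr() if sp.issparse(lognorm) else sp.csr_matrix(lognorm)
    E = X.copy()
    E.data = np.expm1(E.data)
    m = np.asarray(E.mean(axis=1)).ravel()
    sq = E.copy()
    sq.data = sq.data ** 2
    var = np.maximum(np.asarray(sq.mean(axis=1)).ravel() - m ** 2, 0.0)
    n = X.shape[1]
    if n > 1:
        var = var * n / (n - 1)
    return np.where(m > 0, var / np.where(m > 0, m, 1.0), 0.0)


def union_top_dispersion(
    lognorm_1, genes_1, lognorm_2, genes_2, n_top: int = 2000
) -> list[str]:
    """Union of each dataset's top-``n_top`` variance-to-mean-ratio genes,
    restricted to the shared gene namespace; ties at the cutoff break by
    gene order."""
    shared = set(genes_1) & set(genes_2)

    def top(lognorm, genes):
        disp = _dispersion(lognorm)
        order = np.argsort(-disp, kind="stable")[: min(n_top, len(genes))]
        return [genes[i] for i in order]

    union: dict[str, None] = {}
    for g in top(lognorm_1, list(genes_1)) + top(lognorm_2, list(genes_2)):
        if g in shared:
            union[g] = None
    return list(union)


@dataclass
class CCAModel:
    shared_genes: list[str]
    cv_embeddings_1: np.ndarray       # cells_1 x n_cv
    cv_embeddings_2: np.ndarray       # cells_2 x n_cv
    canonical_correlations: np.ndarray
    aligned_embeddings_1: np.ndarray
    aligned_embeddings_2: np.ndarray


def _quantile_map(reference: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Map ``values`` onto the empirical distribution of ``reference``
    by rank; monotone and order-preserving."""
    n_ref = reference.size
    n_val = values.size
    ref_sorted = np.sort(reference)
    ref_q = (np.arange(n_ref) + 0.5) / n_ref
    ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    val_q = (ranks + 0.5) / n_val
    return np.interp(val_q, ref_q, ref_sorted)


def run_cca(
    lognorm_1,
    genes_1,
    lognorm_2,
    genes_2,
    genes: list[str],
    n_cv: int = 20,
    cap: float = 10.0,
) -> CCAModel:
    """Canonical vectors of two datasets over a shared gene list.

    Both matrices are gene-standardized (robust capped scaling), the
    cells_1 x cells_2 cross-product is decomposed by SVD, and the left/right
    singular vectors give the paired cell embeddings.  The reported
    canonical correlation of each component is the gene-space Pearson
    correlation of the two pulled-back component patterns, and components
    are ordered by it.  Alignment is a per-component monotone quantile map
    of dataset 2's embedding onto dataset 1's empirical distribution.
    """
    idx1 = {g: i for i, g in enumerate(genes_1)}
    idx2 = {g: i for i, g in enumerate(genes_2)}
    missing = [g for g in genes if g not in idx1 or g not in idx2]
    if missing:
        raise DataError(f"genes absent from one dataset: {missing[:5]}")
    X1 = _dense_rows(lognorm_1, [idx1[g] for g in genes])
    X2 = _dense_rows(lognorm_2, [idx2[g] for g in genes])
    S1 = scale_genes(X1, cap=cap).T  # cells_1 x genes
    S2 = scale_genes(X2, cap=cap).T
    K = S1 @ S2.T
    max_rank = min(K.shape) - 1
    if n_cv > max_rank:
        warnings.warn(f"n_cv={n_cv} exceeds usable rank {max_rank}; truncating")
        n_cv = max_rank
    u, s, vt = svds(K, k=n_cv, v0=np.full(K.shape[1], 1.0 / np.sqrt(K.shape[1])))
    order = np.argsort(-s, kind="stable")
    u, s, v = u[:, order], s[order], vt[order].T
    # fix sign per component: largest-|.| entry of u positive
    for j in range(n_cv):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] *= -1
            v[:, j] *= -1

    # gene-space canonical correlation of each component pair
    ccs = np.empty(n_cv)
    A = S1.T @ u  # genes x n_cv
    B = S2.T @ v
    for j in range(n_cv):
        a, b = A[:, j], B[:, j]
        denom = np.linalg.norm(a - a.mean()) * np.linalg.norm(b - b.mean())
        ccs[j] = float(np.dot(a - a.mean(), b - b.mean()) / denom) if denom > 0 else 0.0
    order = np.argsort(-ccs, kind="stable")
    u, v, ccs = u[:, order], v[:, order], ccs[order]

    e1 = u * np.sqrt(np.maximum(s[order], 0.0))
    e2 = v * np.sqrt(np.maximum(s[order], 0.0))
    aligned_2 = np.column_stack(
        [_quantile_map(e1[:, j], e2[:, j]) for j in range(n_cv)]
    )
    return CCAModel(
        shared_genes=list(genes),
        cv_embeddings_1=e1,
        cv_embeddings_2=e2,
        canonical_correlations=np.clip(ccs, 0.0, 1.0),
        aligned_embeddings_1=e1,
        aligned_embeddings_2=aligned_2,
    )


def _dense_rows(lognorm, rows) -> np.ndarray:
    if sp.issparse(lognorm):
        return np.asarray(lognorm.tocsr()[rows, :].todense(), dtype=np.float64)
    return np.asarray(lognorm)[rows, :].astype(np.float64)
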