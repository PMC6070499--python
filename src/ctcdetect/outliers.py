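"""The outlier-sensitive pass: PCA on uncapped-scaled HVG expression and
automated rare-cell (candidate-CTC) calling in PC space.

A cell whose whole transcriptional program is private to it — a tumor cell
among blood — lands far from everything else on a leading principal
component once gene scaling is left uncapped.  Calling is automated with a
per-PC robust z-score (median/MAD) at a threshold so extreme that
background cells essentially never reach it — the automated analogue of
spotting a dramatic outlier on a PC plot by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import DataError

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


@dataclass
class PCAModel:
    """Exact-SVD PCA of cells over a gene subset."""

    embeddings: np.ndarray          # cells x n_pcs
    loadings: np.ndarray            # genes x n_pcs, unit-norm columns
    explained_variance: np.ndarray  # per PC, non-increasing
    gene_names: list[str]
    barcodes: list[str]

    @property
    def n_pcs(self) -> int:
        return self.embeddings.shape[1]


def run_pca(
    scaled: np.ndarray,
    gene_names: Sequence[str],
    barcodes: Sequence[str],
    hvg_mask: np.ndarray | None = None,
    n_pcs: int = 20,
) -> PCAModel:
    """PCA with cells as observations on the (optionally HVG-restricted) scaled matrix.

    Uses a full (exact) SVD; the per-component sign ambiguity is fixed by
    making each loading column's largest-magnitude entry positive.
    """
    X = np.asarray(scaled, dtype=np.float64)
    names = list(gene_names)
    if hvg_mask is not None:
        hvg_mask = np.asarray(hvg_mask)
        if hvg_mask.dtype == bool:
            hvg_mask = np.flatnonzero(hvg_mask)
        X = X[hvg_mask]
        names = [names[i] for i in hvg_mask]
    obs = X.T  # cells x genes
    max_rank = min(obs.shape)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds max rank {max_rank}; truncating")
        n_pcs = max_rank
    model = PCA(n_components=n_pcs, svd_solver="full")
    emb = model.fit_transform(obs)
    load = model.components_.T  # genes x n_pcs
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            emb[:, j] *= -1
    return PCAModel(emb, load, model.explained_variance_, names, list(barcodes))


def call_outliers(
    pca: PCAModel, n_pcs_test: int = 5, z_threshold: float = 10.0
) -> pd.DataFrame:
    """Flag cells with extreme robust z on any of the leading PCs.

    robust z = |coord - median| / (1.4826 * MAD), per tested PC; a cell is
    flagged when its maximum over tested PCs reaches ``z_threshold``.  PCs
    with zero MAD are skipped with a warning.
    """
    n_cells = pca.embeddings.shape[0]
    if n_cells < 3:
        raise DataError("outlier calling needs at least 3 cells for median/MAD")
    n_test = min(n_pcs_test, pca.n_pcs)
    scores = np.zeros((n_cells, n_test))
    usable = np.zeros(n_test, dtype=bool)
    for j in range(n_test):
        coords = pca.embeddings[:, j]
        med = np.median(coords)
        mad = np.median(np.abs(coords - med))
        if mad == 0:
            warnings.warn(f"PC{j + 1} has zero MAD; skipped for outlier calling")
            continue
        usable[j] = True
        scores[:, j] = np.abs(coords - med) / (MAD_SCALE * mad)
    if usable.any():
        sub = scores[:, usable]
        pcs = np.flatnonzero(usable)
        best = np.argmax(sub, axis=1)
        outlier_score = sub[np.arange(n_cells), best]
        driving_pc = pcs[best] + 1  # 1-based
    else:
        outlier_score = np.zeros(n_cells)
        driving_pc = np.ones(n_cells, dtype=int)
    return pd.DataFrame(
        {
            "barcode": pca.barcodes,
            "outlier_score": outlier_score,
            "flagged": outlier_score >= z_threshold,
            "driving_pc": driving_pc,
        }
    )


def loading_report(
    pca: PCAModel,
    pc: int = 1,
    top_n: int = 20,
    positive_barcodes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes ranked by signed loading on one PC (1-based index).

    If ``positive_barcodes`` (e.g. the flagged outliers) is given, the
    component is oriented so those cells sit on the positive side; the top
    of the report then reads as the genes defining the outliers.
    """
    if not 1 <= pc <= pca.n_pcs:
        raise ValueError(f"pc={pc} outside 1..{pca.n_pcs}")
    j = pc - 1
    load = pca.loadings[:, j].copy()
    if positive_barcodes:
        pos = [pca.barcodes.index(b) for b in positive_barcodes]
        if pca.embeddings[pos, j].mean() < 0:
            load = -load
    order = np.argsort(-load, kind="stable")[: min(top_n, len(load))]
    return pd.DataFrame(
        {"gene": [pca.gene_names[i] for i in order], "loading": load[order]}
    )


def residual_de_score(
    scaled: np.ndarray,
    gene_names: Sequence[str],
    barcodes: Sequence[str],
    target_barcodes: Sequence[str],
) -> pd.DataFrame:
    """Scaled-residual fold-change proxy for per-cell differential expression.

    score(g) = mean scaled residual over the target cells minus the mean
    over all other cells.  With dropout and no replicates, a formal per-cell
    test is unavailable; this difference of scaled residual means is the
    ranking fed to preranked enrichment analysis.
    """
    barcodes = list(barcodes)
    targets = set(target_barcodes)
    if not targets:
        raise DataError("target_barcodes is empty")
    mask = np.array([b in targets for b in barcodes])
    if mask.sum() != len(targets):
        missing = targets - set(barcodes)
        raise DataError(f"target barcodes not found: {sorted(missing)[:5]}")
    if mask.all():
        raise DataError("target cells must be a proper subset of all cells")
    X = np.asarray(scaled, dtype=np.float64)
    score = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
    df = pd.DataFrame({"gene": list(gene_names), "score": score})
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def top_expressed_overlap(
    lognorm,
    gene_names: Sequence[str],
    barcodes: Sequence[str],
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    n_top: int = 100,
) -> dict:
    """Overlap of the two groups' top-``n_top`` expressed genes.

    Genes are ranked per group by mean log-normalized expression; ties at
    the cutoff are broken by gene order (deterministic) and reported.
    Returns the shared gene list and the shared fraction |A ∩ B| / n_top.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    X = lognorm.toarray() if hasattr(lognorm, "toarray") else np.asarray(lognorm)
    barcodes = list(barcodes)
    idx = {b: i for i, b in enumerate(barcodes)}

    def top_genes(cells):
        cols = [idx[b] for b in cells]
        means = X[:, cols].mean(axis=1)
        order = np.argsort(-means, kind="stable")
        k = min(n_top, len(order))
        tie = k < len(order) and means[order[k - 1]] == means[order[k]]
        return [gene_names[i] for i in order[:k]], tie

    top_a, tie_a = top_genes(cells_a)
    top_b, tie_b = top_genes(cells_b)
    shared = [g for g in top_a if g in set(top_b)]
    return {
        "shared_genes": shared,
        "fraction": len(shared) / n_top,
        "tie_at_cutoff": tie_a or tie_b,
    }
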