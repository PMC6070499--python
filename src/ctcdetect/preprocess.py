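"""Per-cell QC, filtering, normalization and highly-variable-gene selection.

Two parameterizations of the same stack are used downstream:

* the *outlier pass* — every gene kept (``min_cells=0``), scaling without an
  upper cap, HVG selection with no lower mean bound — tuned to preserve the
  subtle, few-cell signal of rare tumor cells;
* the *robust pass* — genes detected in >= 5 cells, scaled values capped —
  the conventional parameterization for stable clustering of the abundant
  blood populations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, DataError

MITO_PREFIX = "MT-"


def compute_qc(counts: CountMatrix) -> pd.DataFrame:
    """Per-cell n_umi, n_gene and mitochondrial UMI fraction (0-1).

    Mitochondrial content uses the standard ``MT-`` symbol prefix.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise DataError("empty count matrix")
    mat = counts.matrix
    n_umi = np.asarray(mat.sum(axis=0)).ravel()
    n_gene = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito_mask = np.array(
        [g.startswith(MITO_PREFIX) for g in counts.gene_symbols], dtype=bool
    )
    if not mito_mask.any():
        warnings.warn("no 'MT-' genes found; pct_mito set to 0 for all cells")
        pct_mito = np.zeros(counts.n_cells)
    else:
        mito_umi = np.asarray(mat[mito_mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_mito = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "n_umi": n_umi.astype(np.int64),
            "n_gene": n_gene.astype(np.int64),
            "pct_mito": pct_mito,
        }
    ).set_index("barcode")


def filter_cells(counts: CountMatrix, qc: pd.DataFrame, min_genes: int = 200) -> CountMatrix:
    """Keep cells with strictly more than ``min_genes`` detected genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    keep = (qc["n_gene"].to_numpy() > min_genes)
    if not keep.any():
        raise DataError(f"no cells retained at min_genes={min_genes}")
    return counts.subset_cells(keep)


def filter_genes(counts: CountMatrix, min_cells: int = 0) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    ``min_cells=0`` is the identity — the outlier pass considers every gene
    regardless of how few cells express it.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    if min_cells == 0:
        return counts
    detected = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    return counts.subset_genes(detected >= min_cells)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> sp.csr_matrix:
    """ln(1 + scale_factor * count / cell_total), genes x cells, sparse.

    All-zero cells map to all-zero columns.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    mat = counts.matrix.astype(np.float64).tocsc()
    totals = np.asarray(mat.sum(axis=0)).ravel()
    inv = np.where(totals > 0, scale_factor / np.maximum(totals, 1.0), 0.0)
    mat = mat @ sp.diags(inv)
    mat.data = np.log1p(mat.data)
    return mat.tocsr()


def regress_covariates(lognorm, qc: pd.DataFrame) -> np.ndarray:
    """OLS residuals of each gene's log expression on [1, n_umi, pct_mito].

    Residuals come back pure (intercept not re-added): downstream scaling
    re-centers per gene anyway.  Zero-variance covariates are dropped with a
    warning; constant genes yield all-zero residual rows.
    """
    Y = np.asarray(lognorm.todense() if sp.issparse(lognorm) else lognorm, dtype=np.float64)
    n_genes, n_cells = Y.shape
    if len(qc) != n_cells:
        raise DataError(f"QC table has {len(qc)} rows for {n_cells} cells")
    cols = [np.ones(n_cells)]
    for name in ("n_umi", "pct_mito"):
        v = qc[name].to_numpy(dtype=np.float64)
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped from the design")
            continue
        cols.append(v)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return (Y.T - X @ beta).T


def scale_genes(mat, cap: float | None = None) -> np.ndarray:
    """Center each gene to mean 0, divide by its SD; optionally clip to [-cap, cap].

    Uncapped scaling is what lets genes expressed in only a handful of cells
    reach extreme z-values and dominate a principal component; the capped
    variant is used for robust clustering.  Zero-variance genes become
    all-zero rows.
    """
    X = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=np.float64)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True) if X.shape[1] > 1 else np.zeros_like(mean)
    out = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if cap is not None:
        if cap <= 0:
            raise ValueError("cap must be positive")
        out = np.clip(out, -cap, cap)
    return out


def select_hvg(
    lognorm,
    n_bins: int = 30,
    z_cutoff: float = 1.0,
    min_mean: float | None = None,
) -> pd.DataFrame:
    """Binned-dispersion highly-variable-gene selection.

    Dispersion is the variance-to-mean ratio of the de-logged expression
    (``expm1`` of the log-normalized values); genes are split into
    ``n_bins`` equal-frequency bins of mean log expression and the
    dispersion is z-standardized within each bin.  A gene is selected when
    its within-bin z meets ``z_cutoff`` and (if given) its mean log
    expression meets ``min_mean``.  The outlier pass runs with
    ``min_mean=None`` so that genes expressed by only a few cells — the rare
    cells' entire program — stay eligible.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    X = lognorm.tocsr() if sp.issparse(lognorm) else sp.csr_matrix(lognorm)
    n_genes, n_cells = X.shape
    mean_log = np.asarray(X.mean(axis=1)).ravel()

    E = X.copy()
    E.data = np.expm1(E.data)
    m = np.asarray(E.mean(axis=1)).ravel()
    sq = E.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - m ** 2, 0.0)
    if n_cells > 1:  # unbiased variance
        var = var * n_cells / (n_cells - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(m > 0, var / np.where(m > 0, m, 1.0), 0.0)

    expressed = m > 0
    bins = np.zeros(n_genes, dtype=np.int64)
    idx = np.flatnonzero(expressed)
    if idx.size:
        order = idx[np.argsort(mean_log[idx], kind="stable")]
        # equal-frequency bins 1..n_bins, ties broken by gene order
        b = np.minimum((np.arange(idx.size) * n_bins) // idx.size, n_bins - 1) + 1
        bins[order] = b

    z = np.zeros(n_genes)
    for bin_id in range(1, n_bins + 1):
        members = np.flatnonzero(bins == bin_id)
        if members.size == 0:
            continue
        if members.size == 1:
            z[members] = 0.0
            continue
        d = dispersion[members]
        sd = d.std(ddof=1)
        z[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    selected = expressed & (z >= z_cutoff)
    if min_mean is not None:
        selected &= mean_log >= min_mean
    return pd.DataFrame(
        {
            "mean_expr": mean_log,
            "dispersion": dispersion,
            "bin": bins,
            "z_dispersion": z,
            "selected": selected,
        }
    )
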