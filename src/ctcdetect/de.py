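"""Grouped single-cell differential expression and marker statistics.

The workhorse test is a bimodal (hurdle) likelihood-ratio test: per gene,
expression is modelled as a Bernoulli detection component times a Normal on
the positive log-normalized values, with the Normal variance pooled across
groups.  Marker ranking uses the area under the ROC curve (one cluster vs
the rest), and multiplicity is handled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

VAR_FLOOR = 1e-6  # variance floor for groups where a gene is barely detected


def _dense(mat) -> np.ndarray:
    return np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=np.float64)


def _bernoulli_ll(k: np.ndarray, n: int) -> np.ndarray:
    """Maximized Bernoulli log-likelihood, with 0*log(0) = 0."""
    k = np.asarray(k, dtype=np.float64)
    p = k / n
    logp = np.zeros_like(p)
    np.log(p, out=logp, where=p > 0)
    log1mp = np.zeros_like(p)
    np.log1p(-p, out=log1mp, where=p < 1)
    return k * logp + (n - k) * log1mp


def _normal_profile_ll(k: np.ndarray, rss: np.ndarray) -> np.ndarray:
    """Maximized Normal log-likelihood for k points with residual SS ``rss``."""
    sigma2 = np.where(k > 0, rss / np.maximum(k, 1), 0.0)
    sigma2 = np.maximum(sigma2, VAR_FLOOR)
    return np.where(k > 0, -0.5 * k * (np.log(2 * np.pi * sigma2) + 1.0), 0.0)


def bimod_lrt(lognorm, gene_names, group_a: np.ndarray, group_b: np.ndarray) -> pd.DataFrame:
    """Hurdle LRT of group A vs group B, one row per gene.

    Null: shared detection rate and shared Normal(mu, sigma^2) on positives.
    Alternative: per-group detection rate and mean, sigma pooled across
    groups.  Deviance ~ chi-square with 2 df.  Genes undetected in both
    groups get p = 1.
    """
    X = _dense(lognorm)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")

    def group_stats(cols):
        x = X[:, cols]
        d = x > 0
        k = d.sum(axis=1)
        s = np.where(d, x, 0.0).sum(axis=1)
        ss = np.where(d, x * x, 0.0).sum(axis=1)
        mu = np.where(k > 0, s / np.maximum(k, 1), 0.0)
        rss = np.maximum(ss - k * mu ** 2, 0.0)
        return k, s, ss, mu, rss, x.mean(axis=1)

    nA, nB = group_a.size, group_b.size
    kA, sA, ssA, muA, rssA, meanA = group_stats(group_a)
    kB, sB, ssB, muB, rssB, meanB = group_stats(group_b)
    K = kA + kB
    # pooled (null) continuous fit
    mu0 = np.where(K > 0, (sA + sB) / np.maximum(K, 1), 0.0)
    rss0 = np.maximum(ssA + ssB - K * mu0 ** 2, 0.0)

    low_detect = ((kA == 1) | (kB == 1)) & (K > 0)
    if low_detect.any():
        warnings.warn(
            f"{int(low_detect.sum())} genes detected exactly once in a group; "
            f"continuous variance floored at {VAR_FLOOR}"
        )

    ll_alt = (
        _bernoulli_ll(kA, nA)
        + _bernoulli_ll(kB, nB)
        + _normal_profile_ll(K, rssA + rssB)
    )
    ll_null = _bernoulli_ll(kA + kB, nA + nB) + _normal_profile_ll(K, rss0)
    deviance = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(deviance, df=2)
    p = np.where(K == 0, 1.0, p)

    out = pd.DataFrame(
        {
            "gene": list(gene_names),
            "statistic": deviance,
            "p_value": p,
            "fdr": bh_fdr(p),
            "mean_diff": meanA - meanB,
            "pct_in": kA / nA,
            "pct_out": kB / nB,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def auc_markers(lognorm, gene_names, labels) -> pd.DataFrame:
    """One-vs-rest AUC marker ranking for every cluster.

    AUC(gene, cluster) = P(in-cluster expression > out-cluster) + 0.5 P(tie),
    computed with midranks so ties contribute exactly one half.  Genes are
    ranked within each cluster by |AUC - 0.5| descending; singleton clusters
    are computed but flagged low-confidence.
    """
    X = _dense(lognorm)
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest markers")
    n_cells = X.shape[1]
    ranks = stats.rankdata(X, axis=1)  # average midranks per gene
    frames = []
    for cl in clusters:
        mask = labels == cl
        n_in = int(mask.sum())
        n_out = n_cells - n_in
        if n_in == 1:
            warnings.warn(f"cluster {cl!r} is a singleton; AUC is low-confidence")
        r_in = ranks[:, mask].sum(axis=1)
        auc = (r_in - n_in * (n_in + 1) / 2.0) / (n_in * n_out)
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": list(gene_names),
                "auc": auc,
                "low_confidence": n_in == 1,
            }
        )
        df["abs_effect"] = np.abs(df["auc"] - 0.5)
        df = df.sort_values("abs_effect", ascending=False, kind="stable")
        frames.append(df.drop(columns="abs_effect"))
    return pd.concat(frames, ignore_index=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, NaN-propagating."""
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full_like(p, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn(f"{int(nan_mask.sum())} NaN p-values propagated as NaN")
    valid = ~nan_mask
    if valid.any():
        pv = p[valid]
        if pv.min() < 0 or pv.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        out[valid] = multipletests(pv, method="fdr_bh")[1]
    return out
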