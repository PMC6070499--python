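"""Preranked gene-set enrichment analysis with a gene-permutation null.

The enrichment score is the maximum deviation of a weighted
Kolmogorov-Smirnov running sum over the ranked gene list (hits increment
proportionally to |score|^weight, misses decrement uniformly).  Because only
a single "phenotype" exists per comparison (one candidate tumor cell vs all
the rest), the null is built by permuting gene labels, never phenotypes.
NES normalizes each ES by the mean same-sign permuted ES, and the FDR is the
standard same-sign NES-ratio estimator, floored at 1/n_perm.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import GeneSetCollection

MIN_SET_SIZE = 5


def _es_from_hits(hit_positions: np.ndarray, weights: np.ndarray, n_genes: int):
    """Signed max deviation of the running sum; hits given as sorted 0-based
    positions in the ranked list, ``weights`` = |score|^w at every rank."""
    m = hit_positions.size
    w = weights[hit_positions]
    total = w.sum()
    if total == 0:  # all-zero scores: fall back to unweighted hits
        w = np.ones(m)
        total = float(m)
    hit_cum = np.cumsum(w) / total
    miss_rate = 1.0 / (n_genes - m)
    # running-sum value immediately after each hit, and just before each hit
    after = hit_cum - (hit_positions + 1 - np.arange(1, m + 1)) * miss_rate
    before = np.concatenate(([0.0], hit_cum[:-1])) - (
        hit_positions - np.arange(m)
    ) * miss_rate
    candidates = np.concatenate((after, before))
    es = candidates[np.argmax(np.abs(candidates))]
    return float(es), after


def _leading_edge(hit_positions, after, es, ranked_genes):
    if es >= 0:
        j = int(np.argmax(after))
        return [ranked_genes[i] for i in hit_positions[: j + 1]]
    j = int(np.argmin(after))
    return [ranked_genes[i] for i in hit_positions[j:]]


def preranked_gsea(
    ranked_scores: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked GSEA for every set against one ranking.

    ``ranked_scores`` maps gene -> score; it is sorted descending internally
    (ties broken by input order).  Sets are restricted to genes present in
    the ranking; sets falling below 5 genes are skipped with a warning.
    Identical seeds give identical p-values and FDRs.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null estimates will be coarse")
    order = np.argsort(-ranked_scores.to_numpy(), kind="stable")
    ranked_genes = list(ranked_scores.index[order])
    scores = ranked_scores.to_numpy()[order]
    n_genes = len(ranked_genes)
    pos_of = {g: i for i, g in enumerate(ranked_genes)}
    weights = np.abs(scores) ** weight

    rng = np.random.default_rng(seed)
    rows = []
    perm_nes_pool: list[np.ndarray] = []
    for name, genes in sets.items():
        hits = np.array(sorted(pos_of[g] for g in genes if g in pos_of))
        if hits.size == 0:
            warnings.warn(f"set {name!r} has zero overlap with the ranking; skipped")
            continue
        if hits.size < MIN_SET_SIZE:
            warnings.warn(
                f"set {name!r} has {hits.size} genes in the ranking (<{MIN_SET_SIZE}); skipped"
            )
            continue
        if n_genes < 2 * hits.size:
            warnings.warn(f"ranking too short for set {name!r}; skipped")
            continue
        es, after = _es_from_hits(hits, weights, n_genes)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_hits = np.sort(rng.choice(n_genes, size=hits.size, replace=False))
            perm_es[i], _ = _es_from_hits(perm_hits, weights, n_genes)
        pos_mean = perm_es[perm_es > 0].mean() if (perm_es > 0).any() else np.nan
        neg_mean = -perm_es[perm_es < 0].mean() if (perm_es < 0).any() else np.nan

        def normalize(v):
            if v >= 0:
                return v / pos_mean if np.isfinite(pos_mean) else 0.0
            return v / neg_mean if np.isfinite(neg_mean) else 0.0

        nes = normalize(es)
        perm_nes = np.array([normalize(v) for v in perm_es])
        perm_nes_pool.append(perm_nes)
        if es >= 0:
            same = perm_es[perm_es >= 0]
            nominal_p = (same >= es).mean() if same.size else 1.0 / n_perm
        else:
            same = perm_es[perm_es < 0]
            nominal_p = (same <= es).mean() if same.size else 1.0 / n_perm
        nominal_p = max(nominal_p, 1.0 / n_perm)
        rows.append(
            {
                "set": name,
                "size": int(hits.size),
                "es": es,
                "nes": nes,
                "nominal_p": nominal_p,
                "leading_edge": _leading_edge(hits, after, es, ranked_genes),
            }
        )

    if not rows:
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "nominal_p", "fdr", "leading_edge"]
        )
    result = pd.DataFrame(rows)
    pool = np.concatenate(perm_nes_pool)
    obs = result["nes"].to_numpy()
    fdr = np.empty(len(result))
    for i, nes in enumerate(obs):
        if nes >= 0:
            num_pool = pool[pool >= 0]
            num = (num_pool >= nes).mean() if num_pool.size else 0.0
            den_obs = obs[obs >= 0]
            den = (den_obs >= nes).mean()
        else:
            num_pool = pool[pool < 0]
            num = (num_pool <= nes).mean() if num_pool.size else 0.0
            den_obs = obs[obs < 0]
            den = (den_obs <= nes).mean()
        fdr[i] = num / den if den > 0 else 1.0
    result["fdr"] = np.clip(fdr, 1.0 / n_perm, 1.0)
    result = result[["set", "size", "es", "nes", "nominal_p", "fdr", "leading_edge"]]
    return result.sort_values("nes", ascending=False, kind="stable").reset_index(drop=True)


def gsea_table_for_tsv(result: pd.DataFrame) -> pd.DataFrame:
    """Comma-join the leading edge for flat-file output."""
    out = result.copy()
    out["leading_edge"] = out["leading_edge"].map(",".join)
    return out
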