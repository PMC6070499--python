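"""End-to-end pipeline stages with a declarative config and reproducible outputs.

Every stage writes its intermediates as TSV under an output directory, each
file carrying a comment header that names the producing operation and the
hash of the resolved configuration; the resolved config itself is echoed
verbatim next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, gsea, integrate, outliers, preprocess, sim
from .io import (
    CountMatrix,
    DataError,
    read_gmt,
    read_mtx_triplet,
    write_gmt,
    write_mtx_triplet,
    write_table,
)

log = logging.getLogger("ctcdetect")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults."""

    # synthetic data
    n_cells: int = 5000
    n_rare: int = 3
    n_genes: int = 2000
    program_size: int = 35
    pop_log2fc: float = 1.5
    rare_log2fc: float = 6.0
    # preprocessing
    scale_factor: float = 1e4
    min_genes: int = 200
    min_cells: int = 5
    n_bins: int = 30
    z_cutoff: float = 1.0
    min_mean: float | None = None
    cap: float = 10.0
    # outlier pass
    n_pcs: int = 20
    n_pcs_test: int = 5
    z_threshold: float = 10.0
    # robust pass / integration
    k: int = 30
    resolution: float = 0.8
    perplexity: float = 30.0
    n_cv: int = 20
    n_top_dispersion: int = 2000
    # GSEA
    n_perm: int = 1000
    weight: float = 1.0
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )


def _stamp(config: PipelineConfig, op: str) -> str:
    return f"producer: {op}\nconfig_hash: {config.config_hash()}"


def cmd_simulate(config: PipelineConfig, outdir, force: bool = False) -> Path:
    """Generate a synthetic patient sample: MTX triplet + truth table + GMT."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise DataError(f"output directory {outdir} is not empty (use force)")
    sc = sim.SimConfig(
        n_cells=config.n_cells,
        n_rare=config.n_rare,
        n_genes=config.n_genes,
        program_size=config.program_size,
        pop_log2fc=config.pop_log2fc,
        rare_log2fc=config.rare_log2fc,
        seed=config.seed,
    )
    cm, truth = sim.generate_dataset(sc)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(cm, outdir)
    sim.write_truth(truth, outdir / "truth.tsv")
    sets = sim.emit_gene_sets(truth, seed=config.seed)
    write_gmt(sets, outdir / "sets.gmt")
    config.echo(outdir)
    log.info("simulated %d cells x %d genes -> %s", cm.n_cells, cm.n_genes, outdir)
    return outdir


def _load_counts(input_dir) -> CountMatrix:
    return read_mtx_triplet(input_dir)


def run_outlier_pass(counts: CountMatrix, config: PipelineConfig) -> dict:
    """The outlier-sensitive pass on one sample, in memory.

    QC -> cell filter -> log-normalize -> covariate regression -> uncapped
    scaling -> HVG (no lower mean bound) -> PCA on HVGs -> robust-z outlier
    calls; plus PC1 loading report and per-outlier residual DE rankings.
    """
    qc = preprocess.compute_qc(counts)
    filtered = preprocess.filter_cells(counts, qc, min_genes=config.min_genes)
    qc = qc.loc[filtered.barcodes]
    lognorm = preprocess.lognormalize(filtered, scale_factor=config.scale_factor)
    residual = preprocess.regress_covariates(lognorm, qc)
    scaled = preprocess.scale_genes(residual, cap=None)
    hvg = preprocess.select_hvg(
        lognorm, n_bins=config.n_bins, z_cutoff=config.z_cutoff, min_mean=config.min_mean
    )
    pca = outliers.run_pca(
        scaled,
        filtered.gene_symbols,
        filtered.barcodes,
        hvg_mask=hvg["selected"].to_numpy(),
        n_pcs=config.n_pcs,
    )
    calls = outliers.call_outliers(
        pca, n_pcs_test=config.n_pcs_test, z_threshold=config.z_threshold
    )
    flagged = list(calls.loc[calls["flagged"], "barcode"])
    report = outliers.loading_report(
        pca, pc=1, top_n=20, positive_barcodes=flagged or None
    )
    de_scores = {
        bc: outliers.residual_de_score(
            scaled, filtered.gene_symbols, filtered.barcodes, [bc]
        )
        for bc in flagged
    }
    return {
        "counts": filtered,
        "qc": qc,
        "lognorm": lognorm,
        "residual": residual,
        "scaled": scaled,
        "hvg": hvg,
        "pca": pca,
        "calls": calls,
        "flagged": flagged,
        "loading_report": report,
        "de_scores": de_scores,
    }


def cmd_outlier_pass(config: PipelineConfig, input_dir, outdir) -> dict:
    """Outlier pass on a triplet directory; writes every intermediate."""
    outdir = Path(outdir)
    counts = _load_counts(input_dir)
    res = run_outlier_pass(counts, config)
    config.echo(outdir)
    write_table(res["qc"].reset_index(), outdir / "qc.tsv", _stamp(config, "compute_qc"))
    write_table(res["hvg"].assign(gene=res["counts"].gene_symbols),
                outdir / "hvg.tsv", _stamp(config, "select_hvg"))
    emb = pd.DataFrame(
        res["pca"].embeddings,
        columns=[f"PC{i + 1}" for i in range(res["pca"].n_pcs)],
    )
    emb.insert(0, "barcode", res["pca"].barcodes)
    write_table(emb, outdir / "pca_embeddings.tsv", _stamp(config, "run_pca"))
    write_table(res["calls"], outdir / "outlier_calls.tsv", _stamp(config, "call_outliers"))
    write_table(res["loading_report"], outdir / "pc1_loadings.tsv",
                _stamp(config, "loading_report"))

    if not res["flagged"]:
        (outdir / "no_candidate_ctcs.txt").write_text(
            "no candidate CTCs: no cell exceeded the outlier threshold\n"
        )
        log.info("no candidate CTCs in %s", input_dir)
        return res

    gmt_path = Path(input_dir) / "sets.gmt"
    if gmt_path.exists():
        sets = read_gmt(gmt_path)
        gsea_tables = {}
        for bc, table in res["de_scores"].items():
            ranking = pd.Series(
                table["score"].to_numpy(), index=table["gene"].to_numpy()
            )
            g = gsea.preranked_gsea(
                ranking, sets, weight=config.weight,
                n_perm=config.n_perm, seed=config.seed,
            )
            gsea_tables[bc] = g
            write_table(gsea.gsea_table_for_tsv(g), outdir / f"gsea_{bc}.tsv",
                        _stamp(config, "preranked_gsea"))
        res["gsea"] = gsea_tables
    for bc, table in res["de_scores"].items():
        write_table(table, outdir / f"residual_de_{bc}.tsv",
                    _stamp(config, "residual_de_score"))
    log.info("flagged %d candidate CTCs", len(res["flagged"]))
    return res


def run_robust_pass(
    counts: CountMatrix,
    config: PipelineConfig,
    outlier_calls: pd.DataFrame | None = None,
    do_tsne: bool = True,
    do_markers: bool = True,
) -> dict:
    """The robust pass: gene filter, capped scaling, PCA on all kept genes,
    kNN graph + modularity clustering, supervised CTC labels, tSNE, markers."""
    qc = preprocess.compute_qc(counts)
    filtered = preprocess.filter_cells(counts, qc, min_genes=config.min_genes)
    qc = qc.loc[filtered.barcodes]
    filtered = preprocess.filter_genes(filtered, min_cells=config.min_cells)
    lognorm = preprocess.lognormalize(filtered, scale_factor=config.scale_factor)
    residual = preprocess.regress_covariates(lognorm, qc)
    scaled = preprocess.scale_genes(residual, cap=config.cap)
    pca = outliers.run_pca(
        scaled, filtered.gene_symbols, filtered.barcodes, n_pcs=config.n_pcs
    )
    graph = integrate.knn_graph(
        pca.embeddings,
        k=min(config.k, pca.embeddings.shape[0] - 1),
        names=filtered.barcodes,
    )
    membership = integrate.modularity_cluster(
        graph, resolution=config.resolution, seed=config.seed
    )
    clusters = pd.DataFrame({"barcode": filtered.barcodes, "cluster": membership})
    if outlier_calls is not None:
        labels = integrate.supervised_label(clusters, outlier_calls)
    else:
        labels = clusters.assign(label=clusters["cluster"].astype(str))
    tsne = None
    if do_tsne:
        perplexity = min(config.perplexity, max((filtered.n_cells - 1) / 3 - 1, 2.0))
        coords = integrate.tsne_embed(
            pca.embeddings, perplexity=perplexity, seed=config.seed
        )
        tsne = pd.DataFrame(
            {"barcode": filtered.barcodes, "tsne1": coords[:, 0], "tsne2": coords[:, 1]}
        )
    auc = lrt = None
    if do_markers:
        marker_labels = (
            labels.set_index("barcode").loc[filtered.barcodes, "label"].to_numpy()
        )
        auc = de.auc_markers(lognorm, filtered.gene_symbols, marker_labels)
        lrt_frames = []
        for cl in pd.unique(marker_labels):
            in_mask = marker_labels == cl
            if in_mask.sum() == 0 or (~in_mask).sum() == 0:
                continue
            t = de.bimod_lrt(lognorm, filtered.gene_symbols, in_mask, ~in_mask)
            t.insert(0, "cluster", cl)
            lrt_frames.append(t)
        lrt = pd.concat(lrt_frames, ignore_index=True)
    return {
        "counts": filtered,
        "qc": qc,
        "lognorm": lognorm,
        "pca": pca,
        "clusters": clusters,
        "labels": labels,
        "tsne": tsne,
        "auc_markers": auc,
        "bimod_markers": lrt,
    }


def cmd_robust_pass(
    config: PipelineConfig, input_dir, outdir, outlier_calls_path=None
) -> dict:
    outdir = Path(outdir)
    counts = _load_counts(input_dir)
    calls = None
    if outlier_calls_path is not None and Path(outlier_calls_path).exists():
        calls = pd.read_csv(outlier_calls_path, sep="\t", comment="#")
    res = run_robust_pass(counts, config, outlier_calls=calls)
    config.echo(outdir)
    write_table(res["labels"], outdir / "cluster_labels.tsv",
                _stamp(config, "modularity_cluster+supervised_label"))
    write_table(res["tsne"], outdir / "tsne.tsv", _stamp(config, "tsne_embed"))
    write_table(res["auc_markers"], outdir / "auc_markers.tsv",
                _stamp(config, "auc_markers"))
    write_table(res["bimod_markers"], outdir / "bimod_markers.tsv",
                _stamp(config, "bimod_lrt"))
    log.info("robust pass: %d clusters", res["labels"]["label"].nunique())
    return res


def run_integration(
    counts_1: CountMatrix, counts_2: CountMatrix, config: PipelineConfig
) -> dict:
    """Two-sample combined analysis: top-dispersion gene union, CCA with
    ``n_cv`` canonical vectors, quantile alignment, joint clustering, markers."""
    ln1 = preprocess.lognormalize(counts_1, scale_factor=config.scale_factor)
    ln2 = preprocess.lognormalize(counts_2, scale_factor=config.scale_factor)
    genes = integrate.union_top_dispersion(
        ln1, counts_1.gene_symbols, ln2, counts_2.gene_symbols,
        n_top=config.n_top_dispersion,
    )
    cca = integrate.run_cca(
        ln1, counts_1.gene_symbols, ln2, counts_2.gene_symbols,
        genes, n_cv=config.n_cv, cap=config.cap,
    )
    joint = np.vstack([cca.aligned_embeddings_1, cca.aligned_embeddings_2])
    barcodes = [f"S1:{b}" for b in counts_1.barcodes] + [
        f"S2:{b}" for b in counts_2.barcodes
    ]
    graph = integrate.knn_graph(joint, k=min(config.k, joint.shape[0] - 1),
                                names=barcodes)
    membership = integrate.modularity_cluster(
        graph, resolution=config.resolution, seed=config.seed
    )
    labels = pd.DataFrame({"barcode": barcodes, "cluster": membership})
    shared_idx1 = [counts_1.gene_symbols.index(g) for g in genes]
    shared_idx2 = [counts_2.gene_symbols.index(g) for g in genes]
    joint_ln = np.hstack(
        [
            np.asarray(ln1.tocsr()[shared_idx1].todense()),
            np.asarray(ln2.tocsr()[shared_idx2].todense()),
        ]
    )
    auc = de.auc_markers(joint_ln, genes, membership)
    return {
        "genes": genes,
        "cca": cca,
        "labels": labels,
        "auc_markers": auc,
    }


def cmd_integrate(config: PipelineConfig, input_dir_1, input_dir_2, outdir) -> dict:
    outdir = Path(outdir)
    c1 = _load_counts(input_dir_1)
    c2 = _load_counts(input_dir_2)
    res = run_integration(c1, c2, config)
    config.echo(outdir)
    cca = res["cca"]
    emb = pd.DataFrame(
        np.vstack([cca.aligned_embeddings_1, cca.aligned_embeddings_2]),
        columns=[f"CV{i + 1}" for i in range(cca.aligned_embeddings_1.shape[1])],
    )
    emb.insert(0, "barcode", list(res["labels"]["barcode"]))
    write_table(emb, outdir / "cca_aligned_embeddings.tsv", _stamp(config, "run_cca"))
    write_table(res["labels"], outdir / "joint_clusters.tsv",
                _stamp(config, "modularity_cluster"))
    write_table(res["auc_markers"], outdir / "joint_auc_markers.tsv",
                _stamp(config, "auc_markers"))
    write_table(
        pd.DataFrame({"canonical_correlation": cca.canonical_correlations}),
        outdir / "canonical_correlations.tsv", _stamp(config, "run_cca"),
    )
    return res


def cmd_report(outdir) -> str:
    """One-paragraph run summary from the files present in an output directory."""
    outdir = Path(outdir)
    lines = []
    calls_path = outdir / "outlier_calls.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t", comment="#")
        n = int(calls["flagged"].sum())
        lines.append(
            f"candidate CTCs flagged: {n} of {len(calls)} cells"
            if n else "no candidate CTCs"
        )
    labels_path = outdir / "cluster_labels.tsv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", comment="#")
        lines.append(f"clusters: {labels['label'].nunique()}")
    if not lines:
        lines.append("no recognized outputs found")
    return "\n".join(lines)
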