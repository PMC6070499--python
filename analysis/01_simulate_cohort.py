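#!/usr/bin/env python
"""Simulate the two-patient synthetic cohort plus a tumor-free control.

Writes three 10X-style triplet directories (matrix.mtx / genes.tsv /
barcodes.tsv) with ground-truth tables and matched GMT gene sets under
results/cohort/.  Patient 1 is larger and deeper with two spiked
hepatocyte-like rare cells, patient 2 smaller and shallower with one, and
the control carries none — mirroring a blood draw from a donor without
cancer.
"""

from pathlib import Path

from ctcdetect.io import write_gmt, write_mtx_triplet
from ctcdetect.pipeline import PipelineConfig
from ctcdetect.sim import (
    SimConfig,
    emit_gene_sets,
    generate_dataset,
    two_patient_configs,
    write_truth,
)

SEED = 1
OUT = Path("results/cohort")


def write_sample(cfg: SimConfig, outdir: Path) -> None:
    cm, truth = generate_dataset(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(cm, outdir)
    write_truth(truth, outdir / "truth.tsv")
    write_gmt(emit_gene_sets(truth, seed=cfg.seed), outdir / "sets.gmt")
    n_rare = len(truth.rare_barcodes)
    print(f"{outdir}: {cm.n_cells} cells x {cm.n_genes} genes, {n_rare} spiked rare")


def main() -> None:
    p1, p2 = two_patient_configs(seed=SEED)
    control = SimConfig(n_cells=2000, n_rare=0, seed=SEED * 2 + 3)
    write_sample(p1, OUT / "patient1")
    write_sample(p2, OUT / "patient2")
    write_sample(control, OUT / "control")
    PipelineConfig(seed=SEED).echo(OUT)
    print(f"cohort written under {OUT}")


if __name__ == "__main__":
    main()
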