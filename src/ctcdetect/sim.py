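"""Ground-truthed synthetic droplet scRNA-seq data.

Emulates a CD45-depleted blood sample run on a droplet platform: ~10^3-10^4
nucleated blood cells from six populations (T, B, NK, monocytes, plasmacytoid
dendritic cells, red blood cells), log-normal per-cell library sizes,
a Beta-distributed mitochondrial UMI fraction carried by an ``MT-`` gene
block, and a handful of spiked rare cells expressing a hepatocyte program
(ALB, TTR, FABP1, ... plus the driver-like genes IGF2, SPINK1, SPP1) that is
essentially absent from the blood background.

Counts are drawn gene-wise negative binomial around cell-specific expected
proportions; dropout arises naturally from low means, with no separate
zero-inflation term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection

#: Hepatocyte program carried by the spiked rare cells: liver-physiology
#: transcripts plus driver-like genes seen up-regulated in liver cancer.
HEPATOCYTE_PROGRAM = [
    "ALB", "TTR", "FABP1", "APOH", "FGB", "APOA2", "GSTA1", "SEPP1",
    "APOC1", "HPD", "ORM1", "HULC", "IGF2", "SPINK1", "SPP1",
]

#: Pan-leukocyte genes mildly down-regulated in the rare cells, emulating
#: their CD45-negative phenotype.
PAN_LEUKOCYTE_GENES = ["PTPRC", "B2M", "CD52", "LAPTM5", "CORO1A"]

#: Mitochondrially encoded genes; a contiguous block carrying the per-cell
#: mitochondrial fraction, named with the standard "MT-" prefix.
MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

DEFAULT_CLUSTER_PROPS = {
    "T": 0.35, "B": 0.12, "NK": 0.10, "monocyte": 0.30, "pDC": 0.03, "RBC": 0.10,
}

RARE_LABEL = "RARE"

#: Background weight for hepatocyte transcripts in blood: blood cells do not
#: express hepatic genes, and ambient RNA is out of scope for this generator.
BACKGROUND_HEP_WEIGHT = 0.0

#: Down-weighting of pan-leukocyte genes in rare cells.
LEUKOCYTE_DOWNWEIGHT = 0.25


@dataclass
class SimConfig:
    """Study conditions for one synthetic patient sample."""

    n_cells: int = 5000
    cluster_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_PROPS)
    )
    n_rare: int = 3
    n_genes: int = 2000
    program_size: int = 35
    pop_log2fc: float = 1.5
    rare_log2fc: float = 6.0
    libsize_lognormal_params: tuple[float, float] = (8.3, 0.45)
    nb_dispersion: float = 10.0
    mito_fraction_beta_params: tuple[float, float] = (10.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_rare < 0 or self.n_genes < 0:
            raise ValueError("n_cells, n_rare and n_genes must be non-negative")
        if self.n_rare > self.n_cells:
            raise ValueError(
                f"n_rare={self.n_rare} exceeds n_cells={self.n_cells}: rare cells "
                "must stay rare relative to the blood background"
            )
        total = sum(self.cluster_props.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cluster_props sum to {total}, expected 1")
        params = [
            self.pop_log2fc, self.rare_log2fc, self.nb_dispersion,
            *self.libsize_lognormal_params, *self.mito_fraction_beta_params,
        ]
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite simulation parameters")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class TruthTable:
    """Per-cell ground truth plus the population gene programs."""

    table: pd.DataFrame  # columns: barcode, population
    program_genes: dict[str, list[str]]
    gene_symbols: list[str]

    @property
    def rare_barcodes(self) -> list[str]:
        t = self.table
        return list(t.loc[t["population"] == RARE_LABEL, "barcode"])


def _gene_roster(config: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    programs: dict[str, list[str]] = {}
    roster: list[str] = list(HEPATOCYTE_PROGRAM)
    programs[RARE_LABEL] = list(HEPATOCYTE_PROGRAM)
    roster += MITO_GENES
    roster += PAN_LEUKOCYTE_GENES
    for pop in config.cluster_props:
        genes = [f"{pop}-PRG{i + 1:02d}" for i in range(config.program_size)]
        programs[pop] = genes
        roster += genes
    if len(roster) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for roster of {len(roster)} "
            "program/housekeeping genes"
        )
    roster += [f"GENE{i + 1:04d}" for i in range(config.n_genes - len(roster))]
    return roster, programs


def generate_dataset(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Draw one gene x cell UMI matrix with its ground-truth table.

    Deterministic for a fixed config (single RNG stream seeded from
    ``config.seed``).  Rare cells are appended after the ``n_cells``
    background cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, programs = _gene_roster(config)
    n_genes = len(genes)
    n_total = config.n_cells + config.n_rare

    gene_idx = {g: i for i, g in enumerate(genes)}
    mito_idx = np.array([gene_idx[g] for g in MITO_GENES])
    hep_idx = np.array([gene_idx[g] for g in HEPATOCYTE_PROGRAM])
    leuko_idx = np.array([gene_idx[g] for g in PAN_LEUKOCYTE_GENES])

    if n_total == 0:
        cm = CountMatrix(sp.csr_matrix((n_genes, 0), dtype=np.int64), genes, [])
        truth = TruthTable(
            pd.DataFrame({"barcode": [], "population": []}), programs, genes
        )
        return cm, truth

    # Baseline relative expression weights: heavy-tailed, median ~ 1.  The
    # roster stands in for the detectably-expressed transcriptome, so the
    # low tail is floored: ultra-sparse ambient-like genes are out of scope.
    base_w = np.maximum(rng.lognormal(mean=0.0, sigma=1.25, size=n_genes), 0.05)
    base_w[hep_idx] = BACKGROUND_HEP_WEIGHT  # hepatic genes absent from blood
    # keep mito and leukocyte genes at solid housekeeping-like levels
    base_w[mito_idx] = rng.lognormal(mean=0.7, sigma=0.3, size=len(mito_idx))
    base_w[leuko_idx] = rng.lognormal(mean=1.0, sigma=0.3, size=len(leuko_idx))

    pops = list(config.cluster_props)
    pop_of_cell = rng.choice(
        pops, size=config.n_cells, p=[config.cluster_props[p] for p in pops]
    )
    populations = list(pop_of_cell) + [RARE_LABEL] * config.n_rare
    barcodes = [f"CELL{i + 1:05d}" for i in range(n_total)]

    # Per-cell weight matrix (genes x cells), then normalized to proportions.
    W = np.tile(base_w[:, None], (1, n_total))
    pop_mult = 2.0 ** config.pop_log2fc
    for pop in pops:
        cols = np.flatnonzero(pop_of_cell == pop)
        rows = np.array([gene_idx[g] for g in programs[pop]])
        W[np.ix_(rows, cols)] *= pop_mult
    if config.n_rare:
        rare_cols = np.arange(config.n_cells, n_total)
        # Rare-cell hepatocyte program anchored at 2^rare_log2fc times a
        # typical (median-weight) gene; the blood background stays ambient.
        W[np.ix_(hep_idx, rare_cols)] = 2.0 ** config.rare_log2fc
        W[np.ix_(leuko_idx, rare_cols)] *= LEUKOCYTE_DOWNWEIGHT

    # Mitochondrial fraction: per-cell Beta draw, mito block rescaled to
    # consume exactly that expected fraction of the library.
    a, b = config.mito_fraction_beta_params
    mito_frac = rng.beta(a, b, size=n_total)
    non_mito = np.ones(n_genes, dtype=bool)
    non_mito[mito_idx] = False
    P = np.empty_like(W)
    sum_non = W[non_mito].sum(axis=0)
    sum_mito = W[mito_idx].sum(axis=0)
    P[non_mito] = W[non_mito] * ((1.0 - mito_frac) / sum_non)
    P[mito_idx] = W[mito_idx] * (mito_frac / sum_mito)

    mu_log, sd_log = config.libsize_lognormal_params
    libsize = rng.lognormal(mean=mu_log, sigma=sd_log, size=n_total)

    mu = P * libsize  # expected counts per gene per cell
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(sp.csr_matrix(counts), genes, barcodes)
    truth = TruthTable(
        pd.DataFrame({"barcode": barcodes, "population": populations}),
        programs,
        genes,
    )
    return cm, truth


def emit_gene_sets(
    truth: TruthTable,
    n_decoys: int = 20,
    decoy_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """One GMT set per population program plus random decoy sets.

    Decoys are drawn from the non-program gene universe so truth recovery in
    enrichment tests is unambiguous.  Programs below 5 genes are omitted with
    a warning (enrichment on tiny sets is meaningless).
    """
    if not truth.program_genes:
        raise ValueError("truth table has no populations")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    program_members = {g for genes in truth.program_genes.values() for g in genes}
    for pop, genes in truth.program_genes.items():
        if len(genes) < 5:
            warnings.warn(f"program {pop!r} has {len(genes)} genes (<5); set omitted")
            continue
        sets[f"PRG_{pop}"] = list(genes)
    universe = [g for g in truth.gene_symbols if g not in program_members]
    for i in range(n_decoys):
        size = min(decoy_size, len(universe))
        if size < 5:
            warnings.warn("gene universe too small for decoy sets")
            break
        members = rng.choice(universe, size=size, replace=False)
        sets[f"DECOY_{i + 1:02d}"] = [str(g) for g in members]
    return GeneSetCollection(sets)


def two_patient_configs(seed: int = 0) -> tuple[SimConfig, SimConfig]:
    """Study conditions for the two-sample combined analysis.

    Two patients with different sequencing regimes: the first larger and
    deeper, carrying two spiked rare cells; the second smaller and
    shallower, carrying one — a scaled-down version of a two-patient
    droplet study with 1-3 tumor cells per sample.
    """
    p1 = SimConfig(n_cells=2400, n_rare=2, seed=seed * 2 + 1)
    p2 = SimConfig(
        n_cells=1600,
        n_rare=1,
        libsize_lognormal_params=(8.0, 0.5),
        seed=seed * 2 + 2,
    )
    return p1, p2


def write_truth(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path, program_genes: dict[str, list[str]] | None = None,
               gene_symbols: Sequence[str] | None = None) -> TruthTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return TruthTable(table, program_genes or {}, list(gene_symbols or []))
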