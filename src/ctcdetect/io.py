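"""Readers and writers for the formats the pipeline touches.

Count matrices travel as 10X-style Matrix Market triplets
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) or dense TSV;
gene sets as GMT; result tables as TSV with a comment header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def dedup_symbols(symbols: Sequence[str]) -> list[str]:
    """Make symbols unique by suffixing repeats with ``.1``, ``.2``, ...

    Keeps every row of the matrix; the first occurrence keeps its bare name.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI matrix, genes x cells."""

    matrix: sp.csr_matrix
    gene_symbols: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_symbols = list(self.gene_symbols)
        self.barcodes = list(self.barcodes)
        ng, nc = self.matrix.shape
        if ng != len(self.gene_symbols):
            raise DataError(
                f"matrix has {ng} rows but {len(self.gene_symbols)} gene symbols"
            )
        if nc != len(self.barcodes):
            raise DataError(f"matrix has {nc} columns but {len(self.barcodes)} barcodes")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise DataError("count matrix has negative entries")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            self.gene_symbols = dedup_symbols(self.gene_symbols)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.matrix[:, index],
            self.gene_symbols,
            [self.barcodes[i] for i in index],
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.matrix[index, :],
            [self.gene_symbols[i] for i in index],
            self.barcodes,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), insertion-ordered."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Matrix Market triplet


def read_mtx_triplet(dir_path) -> CountMatrix:
    """Read a 10X-style triplet directory into a genes x cells CountMatrix.

    The on-disk orientation is inferred from the label-file lengths; 1-based
    Matrix Market indices become 0-based internally.  Real-valued files are
    accepted as long as every stored entry is integral.
    """
    dir_path = Path(dir_path)
    mtx_path = dir_path / "matrix.mtx"
    genes_path = dir_path / "genes.tsv"
    barcodes_path = dir_path / "barcodes.tsv"
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise DataError(f"missing file: {p}")

    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.nnz and np.any(mat.data != np.round(mat.data)):
            raise DataError(f"{mtx_path}: non-integer entries in count matrix")
        mat = mat.astype(np.int64)

    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    symbols = list(genes_df.iloc[:, -1])
    barcodes = [
        line.strip() for line in barcodes_path.read_text().splitlines() if line.strip()
    ]

    ng, nc = len(symbols), len(barcodes)
    if mat.shape == (ng, nc):
        pass
    elif mat.shape == (nc, ng):
        mat = mat.T.tocsr()
    else:
        raise DataError(
            f"{mtx_path}: shape {mat.shape} matches neither genes.tsv ({ng}) "
            f"x barcodes.tsv ({nc}) nor its transpose"
        )
    return CountMatrix(mat, dedup_symbols(symbols), barcodes)


def write_mtx_triplet(cm: CountMatrix, dir_path, gene_ids: Sequence[str] | None = None) -> None:
    """Write ``matrix.mtx`` (integer field, genes x cells), ``genes.tsv``, ``barcodes.tsv``."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mat = cm.matrix.tocoo().astype(np.int64)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), mat, field="integer")
    ids = list(gene_ids) if gene_ids is not None else cm.gene_symbols
    with open(dir_path / "genes.tsv", "w") as fh:
        for gid, sym in zip(ids, cm.gene_symbols):
            fh.write(f"{gid}\t{sym}\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for bc in cm.barcodes:
            fh.write(bc + "\n")


def read_dense_tsv(path) -> CountMatrix:
    """Read a dense genes-in-rows TSV (first column = gene symbol, header = barcodes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.all(values == np.round(values)):
        raise DataError(f"{path}: non-integer entries in count matrix")
    if (values < 0).any():
        raise DataError(f"{path}: negative entries in count matrix")
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        dedup_symbols([str(g) for g in df.index]),
        [str(c) for c in df.columns],
    )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Parse GMT: ``name TAB description TAB gene...`` per line.

    Duplicate genes within a set collapse to the first occurrence; lines with
    fewer than three fields are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{lineno}: fewer than 3 fields, skipping line")
                continue
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Result tables


def write_table(df: pd.DataFrame, path, comment: str | None = None, index: bool = False) -> None:
    """Write a TSV result table, optionally preceded by ``# comment`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
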