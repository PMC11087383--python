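"""Sparse gene-by-cell matrix containers and 10x-style MTX triple I/O.

The raw substrate of the pipeline is a UMI count matrix over gene symbols
and cell barcodes, stored genes x cells. On disk it is the conventional
10x triple: a MatrixMarket coordinate file plus features and barcodes TSVs,
each optionally gzipped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class MatrixError(ValueError):
    """Raised for structurally invalid matrices or on-disk triples."""


@dataclass
class CountMatrix:
    """Non-negative integer UMI counts, genes x cells.

    Parameters
    ----------
    genes
        Ordered gene symbols (unique).
    barcodes
        Ordered cell barcodes (unique).
    counts
        ``(n_genes, n_cells)`` sparse CSR matrix of non-negative integers.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise MatrixError("duplicate gene symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixError("duplicate cell barcodes")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise MatrixError("negative counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise MatrixError("non-integer counts")
        self._gene_index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_row(self, symbol: str) -> np.ndarray:
        """Dense counts for one gene across all cells."""
        try:
            i = self._gene_index[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None
        return np.asarray(self.counts[i].todense()).ravel()

    def subset_cells(self, keep: list[str] | set[str]) -> "CountMatrix":
        """Restrict to the given barcodes, preserving current order."""
        keep = set(keep)
        idx = [j for j, b in enumerate(self.barcodes) if b in keep]
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[j] for j in idx],
            counts=self.counts[:, idx].tocsr(),
        )


@dataclass
class NormMatrix:
    """Log-normalized expression with the same axes as a :class:`CountMatrix`.

    Values are ``ln(1 + count / cell_total * scale_factor)``; zeros are
    preserved exactly, so the sparsity pattern matches the raw counts.
    """

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix
    scale_factor: float = 10_000.0
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixError("values shape does not match axes")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_row(self, symbol: str) -> np.ndarray:
        try:
            i = self._gene_index[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None
        return np.asarray(self.values[i].todense()).ravel()


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"neither {stem} nor {stem}.gz found in {dirpath}")


def read_counts_10x(path: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triple from a directory.

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, each optionally ``.gz``. The features file may have one
    column (symbol) or two-plus columns (id, symbol, ...); symbols come from
    the second column when present. Orientation on disk may be genes x cells
    or cells x genes; it is inferred from the features/barcodes line counts.
    """
    dirpath = Path(path)
    if not dirpath.is_dir():
        raise FileNotFoundError(f"matrix directory {dirpath} does not exist")
    mtx_path = _find(dirpath, "matrix.mtx")
    try:
        feat_path = _find(dirpath, "features.tsv")
    except FileNotFoundError:
        feat_path = _find(dirpath, "genes.tsv")
    bc_path = _find(dirpath, "barcodes.tsv")

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    genes = list(feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0])
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise MatrixError(f"duplicate barcodes in {bc_path}")

    with _open_maybe_gz(mtx_path) as fh:
        m = scipy.io.mmread(fh)
    m = sp.csr_matrix(m)
    if m.shape == (len(genes), len(barcodes)):
        pass
    elif m.shape == (len(barcodes), len(genes)):
        m = m.T.tocsr()
    else:
        raise MatrixError(
            f"matrix shape {m.shape} inconsistent with {len(genes)} features "
            f"and {len(barcodes)} barcodes"
        )
    if m.data.size and not np.allclose(m.data, np.round(m.data)):
        raise MatrixError("matrix contains non-integer values")
    return CountMatrix(genes=genes, barcodes=barcodes, counts=m)


def write_counts_10x(cm: CountMatrix, path: str | Path, gz: bool = False) -> None:
    """Write a :class:`CountMatrix` as a 10x MTX triple (genes x cells)."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gz else ""

    mtx_path = dirpath / ("matrix.mtx" + suffix)
    opener = gzip.open if gz else open
    with opener(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(_as_int(cm.counts)))
    with opener(dirpath / ("features.tsv" + suffix), "wt") as fh:  # type: ignore[arg-type]
        for g in cm.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with opener(dirpath / ("barcodes.tsv" + suffix), "wt") as fh:  # type: ignore[arg-type]
        for b in cm.barcodes:
            fh.write(b + "\n")


def _as_int(m: sp.spmatrix) -> sp.spmatrix:
    m = m.copy()
    m.data = np.round(m.data).astype(np.int64)
    return m
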