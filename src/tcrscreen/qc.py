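"""Per-cell quality control and log-normalization.

Cells are gated on three criteria computed from raw UMI counts: detected
gene number within a window (default 800-10,000, inclusive), mitochondrial
UMI fraction strictly below a cap (default 0.2), and mean raw UMI count of
the CD3 complex genes (CD3D, CD3E, CD3G) strictly above a floor (default 0).
The CD3 mean divides by the number of *configured* CD3 genes, so a CD3 gene
missing from the reference lowers the mean rather than shrinking the
denominator; missing genes trigger a warning, and an error only when none
of them resolve.

Normalization is counts-per-scale-factor followed by natural log1p:
``ln(1 + count / cell_total * scale_factor)``, scale factor 10,000 by
default, applied after filtering so every cell has positive total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .matrix import CountMatrix, NormMatrix

DEFAULT_CD3_GENES = ("CD3D", "CD3E", "CD3G")


@dataclass(frozen=True)
class QcThresholds:
    """Cell-gate thresholds and gene-set rules.

    The gene-number window is inclusive on both ends; the mitochondrial and
    CD3 thresholds are strict inequalities (``pct_mito < max_pct_mito``,
    ``cd3_mean > min_cd3_mean``).
    """

    min_genes: int = 800
    max_genes: int = 10_000
    max_pct_mito: float = 0.2
    min_cd3_mean: float = 0.0
    mito_gene_rule: str = "MT-"
    cd3_genes: tuple[str, ...] = DEFAULT_CD3_GENES
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        if not (0 < self.max_pct_mito <= 1):
            raise ValueError("max_pct_mito must be in (0, 1]")
        if not self.cd3_genes:
            raise ValueError("cd3_genes must be non-empty")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class CellQcMetrics:
    barcode: str
    n_genes_detected: int
    total_umi: int
    pct_mito: float  # fraction in [0, 1]; 0/0 defined as 0
    cd3_mean_umi: float


@dataclass
class QcReport:
    """Per-criterion failure counts (a cell may fail several)."""

    n_total: int
    n_kept: int
    fail_low_genes: int = 0
    fail_high_genes: int = 0
    fail_mito: int = 0
    fail_cd3: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _mito_mask(genes: list[str], prefix: str) -> np.ndarray:
    pfx = prefix.upper()
    return np.array([g.upper().startswith(pfx) for g in genes], dtype=bool)


def compute_cell_qc(counts: CountMatrix, thresholds: QcThresholds | None = None) -> list[CellQcMetrics]:
    """Compute raw-count QC metrics for every cell, in barcode order."""
    thr = thresholds or QcThresholds()
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")

    gene_set = set(counts.genes)
    present_cd3 = [g for g in thr.cd3_genes if g in gene_set]
    missing_cd3 = [g for g in thr.cd3_genes if g not in gene_set]
    if not present_cd3:
        raise ValueError(
            f"none of the configured CD3 genes {list(thr.cd3_genes)} are present in the matrix"
        )
    if missing_cd3:
        warnings.warn(
            f"CD3 genes absent from reference: {missing_cd3}; "
            f"cd3_mean still divides by {len(thr.cd3_genes)}",
            stacklevel=2,
        )

    csc = counts.counts.tocsc()
    total = np.asarray(csc.sum(axis=0)).ravel()
    n_det = np.asarray((csc > 0).sum(axis=0)).ravel()

    mito = _mito_mask(counts.genes, thr.mito_gene_rule)
    mito_total = np.asarray(csc[mito].sum(axis=0)).ravel() if mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    cd3_idx = [counts.genes.index(g) for g in present_cd3]
    cd3_total = np.asarray(csc[cd3_idx].sum(axis=0)).ravel()
    cd3_mean = cd3_total / len(thr.cd3_genes)  # fixed denominator: configured set size

    return [
        CellQcMetrics(
            barcode=b,
            n_genes_detected=int(n_det[j]),
            total_umi=int(total[j]),
            pct_mito=float(pct_mito[j]),
            cd3_mean_umi=float(cd3_mean[j]),
        )
        for j, b in enumerate(counts.barcodes)
    ]


def filter_cells(
    metrics: list[CellQcMetrics], thresholds: QcThresholds | None = None
) -> tuple[set[str], QcReport]:
    """Apply the three-criterion cell gate; returns kept barcodes and a report."""
    thr = thresholds or QcThresholds()
    kept: set[str] = set()
    rep = QcReport(n_total=len(metrics), n_kept=0)
    for m in metrics:
        ok = True
        if m.n_genes_detected < thr.min_genes:
            rep.fail_low_genes += 1
            ok = False
        if m.n_genes_detected > thr.max_genes:
            rep.fail_high_genes += 1
            ok = False
        if not (m.pct_mito < thr.max_pct_mito):
            rep.fail_mito += 1
            ok = False
        if not (m.cd3_mean_umi > thr.min_cd3_mean):
            rep.fail_cd3 += 1
            ok = False
        if ok:
            kept.add(m.barcode)
    rep.n_kept = len(kept)
    return kept, rep


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormMatrix:
    """Counts-per-scale-factor log1p normalization.

    ``value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor)``.
    Every cell must have a positive total (filter first).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    csc = counts.counts.tocsc().astype(np.float64)
    total = np.asarray(csc.sum(axis=0)).ravel()
    zero_cells = np.flatnonzero(total == 0)
    if zero_cells.size:
        bad = [counts.barcodes[j] for j in zero_cells[:5]]
        raise ValueError(f"cells with zero total UMI cannot be normalized: {bad}")
    # scale columns in place on the sparse structure, then log1p on stored values
    inv = scale_factor / total
    csc = csc @ sp.diags(inv)
    csc = csc.tocsr()
    csc.data = np.log1p(csc.data)
    return NormMatrix(
        genes=list(counts.genes),
        barcodes=list(counts.barcodes),
        values=csc,
        scale_factor=scale_factor,
    )
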