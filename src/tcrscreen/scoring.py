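"""Binned-control module scoring of a T-cell activation signature.

The activation score of a cell is the mean log-normalized expression of a
10-gene activation/effector signature (IFNG, IL2, TNF, IL2RA, CD69,
TNFRSF9, GZMB, GZMA, GZMK, PRF1) minus the mean over a control gene set
drawn from expression-matched bins. Binning is deterministic here: genes
are ranked by mean normalized expression across cells, ties broken by gene
symbol, and the ranking is cut into equal-frequency bins (sizes differing
by at most one). For each signature gene, ``n_ctrl`` control genes are
sampled without replacement from its bin (stochastic mode, seeded), or the
entire bins are pooled (deterministic mode, used for oracle testing).
Signature genes are not excluded from their own control bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import NormMatrix

DEFAULT_SIGNATURE = (
    "IFNG", "IL2", "TNF", "IL2RA", "CD69",
    "TNFRSF9", "GZMB", "GZMA", "GZMK", "PRF1",
)

STOCHASTIC = "stochastic"
DETERMINISTIC_FULL_BIN = "deterministic_full_bin"


@dataclass(frozen=True)
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0
    mode: str = STOCHASTIC

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")
        if self.mode not in (STOCHASTIC, DETERMINISTIC_FULL_BIN):
            raise ValueError(f"unknown mode {self.mode!r}")


def validate_signature(genes, matrix_genes: list[str]) -> list[str]:
    sig = list(genes)
    if not sig:
        raise ValueError("empty signature")
    if len(set(sig)) != len(sig):
        raise ValueError("signature contains duplicate genes")
    missing = [g for g in sig if g not in set(matrix_genes)]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    return sig


def bin_genes_by_mean_expression(norm: NormMatrix, n_bins: int = 24) -> dict[str, int]:
    """Assign every gene to an equal-frequency bin of mean expression.

    Bins are numbered from 0 (lowest mean). Ties in mean expression are
    broken by gene symbol ascending, so the assignment is deterministic.
    """
    if norm.n_genes == 0 or norm.n_cells == 0:
        raise ValueError("empty matrix")
    if n_bins > norm.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({norm.n_genes})")
    means = np.asarray(norm.values.mean(axis=1)).ravel()
    order = sorted(range(norm.n_genes), key=lambda i: (means[i], norm.genes[i]))
    assignment: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.array(order), n_bins)):
        for i in chunk:
            assignment[norm.genes[int(i)]] = b
    return assignment


def sample_control_genes(
    bins: dict[str, int],
    signature: list[str],
    n_ctrl: int = 100,
    seed: int = 0,
    mode: str = STOCHASTIC,
) -> list[str]:
    """Pooled control gene multiset for a signature.

    Stochastic mode draws ``min(n_ctrl, bin size)`` genes uniformly without
    replacement from each signature gene's bin (seeded; signature genes are
    eligible). Deterministic mode returns the union of the entire bins,
    each bin contributing once per signature gene it hosts.
    """
    members: dict[int, list[str]] = {}
    for g, b in bins.items():
        members.setdefault(b, []).append(g)
    for b in members:
        members[b].sort()
    missing = [g for g in signature if g not in bins]
    if missing:
        raise ValueError(f"signature genes not binned: {missing}")

    controls: list[str] = []
    rng = np.random.default_rng(seed)
    for g in signature:
        pool = members[bins[g]]
        if mode == DETERMINISTIC_FULL_BIN:
            controls.extend(pool)
        else:
            k = min(n_ctrl, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            controls.extend(pool[i] for i in sorted(idx))
    return controls


def compute_module_score(
    norm: NormMatrix,
    signature=DEFAULT_SIGNATURE,
    params: ModuleScoreParams | None = None,
) -> np.ndarray:
    """Per-cell module score: mean(signature) - mean(control multiset).

    Returns a barcode-aligned float vector (values may be negative).
    """
    params = params or ModuleScoreParams()
    sig = validate_signature(signature, norm.genes)
    bins = bin_genes_by_mean_expression(norm, params.n_bins)
    controls = sample_control_genes(bins, sig, params.n_ctrl, params.seed, params.mode)

    gi = {g: i for i, g in enumerate(norm.genes)}
    sig_rows = [gi[g] for g in sig]
    ctrl_rows = [gi[g] for g in controls]  # multiplicity-weighted
    dense = lambda rows: np.asarray(norm.values[rows].mean(axis=0)).ravel()
    return dense(sig_rows) - dense(ctrl_rows)


def gene_expression(norm: NormMatrix, symbol: str) -> np.ndarray:
    """Barcode-aligned normalized-expression vector of one gene."""
    try:
        return norm.gene_row(symbol)
    except KeyError:
        # suggest the closest symbol to catch case/typo slips
        import difflib

        near = difflib.get_close_matches(symbol, norm.genes, n=1)
        hint = f"; did you mean {near[0]!r}?" if near else ""
        raise KeyError(f"gene {symbol!r} not in matrix{hint}") from None
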