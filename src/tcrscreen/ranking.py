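"""Clonotype-level aggregation, ranking and candidate-panel selection.

Per-cell values (normalized IFNG, normalized TNFRSF9, activation score)
are averaged over all cells of each clonotype. To limit small-sample bias,
only clonotypes carried by at least ``min_cells`` cells (default 3) enter
the ranking; the full table is retained for reporting. Each ranking key
orders clonotypes by descending mean, ties broken by cell count descending
then clonotype_id ascending, and assigns dense ranks 1..N. The candidate
panel takes the top-k clonotypes under each key and merges duplicates, so
a clonotype topping several keys appears once with the union of labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_KEYS = ("IFNG", "TNFRSF9", "SCORE")


@dataclass
class PanelEntry:
    clonotype_id: str
    selected_by: set[str]
    ranks: dict[str, int]  # key -> rank under that key

    @property
    def best_rank(self) -> int:
        return min(self.ranks[k] for k in self.selected_by)


@dataclass
class CandidatePanel:
    entries: list[PanelEntry]
    k: int = 3

    def clonotype_ids(self) -> list[str]:
        return [e.clonotype_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clonotype_id": [e.clonotype_id for e in self.entries],
                "selected_by": [",".join(sorted(e.selected_by)) for e in self.entries],
                **{
                    f"rank_{k.lower()}": [e.ranks.get(k, np.nan) for e in self.entries]
                    for k in RANK_KEYS
                },
            }
        )


def aggregate_by_clonotype(
    values: pd.Series | dict[str, float],
    barcode_to_clonotype: dict[str, str],
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clonotype means of a barcode-aligned value vector.

    Returns ``(ranking_table, full_table)``: both have columns
    ``clonotype_id, mean, n_cells``; the ranking table keeps only
    clonotypes with ``n_cells >= min_cells``. Barcodes without a clonotype
    mapping are dropped with a logged count.
    """
    s = pd.Series(values, dtype=float)
    mapped = s.index.isin(barcode_to_clonotype.keys())
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.info("dropping %d barcodes without clonotype assignment", n_unmapped)
    s = s[mapped]
    if s.empty:
        raise ValueError("no barcode in the value vector has a clonotype mapping")
    cids = s.index.map(barcode_to_clonotype)
    grouped = s.groupby(cids)
    full = pd.DataFrame({"mean": grouped.mean(), "n_cells": grouped.size()})
    full.index.name = "clonotype_id"
    full = full.reset_index()
    ranking = full[full["n_cells"] >= min_cells].reset_index(drop=True)
    return ranking, full


def rank_clonotypes(table: pd.DataFrame, key: str = "SCORE") -> pd.DataFrame:
    """Order a clonotype table by descending mean and assign ranks 1..N.

    Ties: larger ``n_cells`` first, then ``clonotype_id`` ascending. The
    ``key`` label is recorded in the output for provenance.
    """
    if key not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")
    if table.empty:
        raise ValueError("cannot rank an empty clonotype table")
    out = table.sort_values(
        by=["mean", "n_cells", "clonotype_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["key"] = key
    return out


def select_candidate_panel(
    ranked: dict[str, pd.DataFrame], k: int = 3
) -> CandidatePanel:
    """Top-k per key, deduplicated by clonotype_id.

    ``ranked`` maps a key label to a table from :func:`rank_clonotypes`.
    Entries are ordered by best rank across their selecting keys, ties by
    clonotype_id.
    """
    entries: dict[str, PanelEntry] = {}
    for key, table in ranked.items():
        if k > len(table):
            logger.warning("k=%d exceeds table size %d for key %s; taking all", k, len(table), key)
        top = table.head(k)
        for cid, rank in zip(top["clonotype_id"], top["rank"]):
            if cid in entries:
                entries[cid].selected_by.add(key)
                entries[cid].ranks[key] = int(rank)
            else:
                entries[cid] = PanelEntry(clonotype_id=cid, selected_by={key}, ranks={key: int(rank)})
    # fill in cross-key ranks for entries selected under other keys
    for key, table in ranked.items():
        all_ranks = dict(zip(table["clonotype_id"], table["rank"]))
        for e in entries.values():
            if key not in e.ranks and e.clonotype_id in all_ranks:
                e.ranks[key] = int(all_ranks[e.clonotype_id])
    ordered = sorted(entries.values(), key=lambda e: (e.best_rank, e.clonotype_id))
    return CandidatePanel(entries=ordered, k=k)
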