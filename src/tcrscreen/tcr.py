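"""Contig parsing, paired-chain resolution and nucleotide clonotyping.

A cell enters the repertoire analysis only if it carries both a productive
TRA and a productive TRB contig. Cells with several productive chains of
one locus keep the chain with the higher UMI count, then higher read count,
then lexicographically smallest CDR3 nucleotide sequence (a total, order-
independent tie cascade). Clonotypes are equivalence classes of cells whose
retained alpha and beta chains are identical at the nucleotide level; by
default the grouping key also includes the V/(D)/J segment calls, with a
CDR3-nucleotide-only alternative.
"""

from __future__ import annotations

import hashlib
import io
import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CONTIG_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "umis",
    "reads",
)

_TRUE_DIALECTS = {"true", "t", "yes", "1"}


class ContigParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChainRecord:
    barcode: str
    locus: str  # TRA or TRB
    v_gene: str
    d_gene: str  # "None" for alpha chains / uncalled D
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    reads: int
    productive: bool


@dataclass(frozen=True)
class PairedTcr:
    barcode: str
    alpha: ChainRecord
    beta: ChainRecord

    def __post_init__(self) -> None:
        if self.alpha.locus != "TRA" or self.beta.locus != "TRB":
            raise ValueError("PairedTcr requires a TRA alpha and TRB beta chain")
        if self.alpha.barcode != self.beta.barcode or self.alpha.barcode != self.barcode:
            raise ValueError("chains of a pair must share the barcode")


@dataclass
class Clonotype:
    clonotype_id: str
    alpha_nt: str
    beta_nt: str
    trav: str
    traj: str
    trbv: str
    trbd: str
    trbj: str
    cdr3_alpha_aa: str
    cdr3_beta_aa: str
    member_barcodes: set[str]

    @property
    def n_cells(self) -> int:
        return len(self.member_barcodes)


def _parse_productive(value) -> bool:
    # Only literal true dialects count; "None"/empty/NaN/false are non-productive.
    if pd.isna(value):
        return False
    return str(value).strip().lower() in _TRUE_DIALECTS


def parse_contigs(source) -> list[ChainRecord]:
    """Parse a 10x-style ``filtered_contig_annotations.csv``.

    ``source`` may be a path, file-like object, or the CSV text itself.
    Rows with loci outside TRA/TRB (e.g. TRG/TRD, IGH) are dropped with a
    logged count; unknown columns are ignored.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ContigParseError(f"contig table missing required columns: {missing}")

    records: list[ChainRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        locus = str(row.chain).strip().upper()
        if locus not in ("TRA", "TRB"):
            n_dropped += 1
            continue
        try:
            umis = int(float(row.umis))
            reads = int(float(row.reads))
        except (TypeError, ValueError) as exc:
            raise ContigParseError(f"unparseable numeric field at data row {i + 1}: {exc}") from None
        records.append(
            ChainRecord(
                barcode=str(row.barcode),
                locus=locus,
                v_gene="" if pd.isna(row.v_gene) else str(row.v_gene),
                d_gene="None" if pd.isna(row.d_gene) or str(row.d_gene) == "" else str(row.d_gene),
                j_gene="" if pd.isna(row.j_gene) else str(row.j_gene),
                cdr3_aa="" if pd.isna(row.cdr3) else str(row.cdr3),
                cdr3_nt="" if pd.isna(row.cdr3_nt) else str(row.cdr3_nt),
                umis=umis,
                reads=reads,
                productive=_parse_productive(row.productive),
            )
        )
    if n_dropped:
        logger.info("dropped %d non-TRA/TRB contig rows", n_dropped)
    return records


def _best_chain(chains: list[ChainRecord]) -> ChainRecord:
    # Higher UMIs, then higher reads, then smallest cdr3_nt: a total order.
    return min(chains, key=lambda c: (-c.umis, -c.reads, c.cdr3_nt))


def resolve_paired_tcr(records: list[ChainRecord]) -> dict[str, PairedTcr | None]:
    """Resolve one productive alpha+beta pair per barcode (or ``None``).

    Non-productive contigs are discarded first; among the surviving chains
    of each locus the tie cascade (umis desc, reads desc, cdr3_nt asc)
    selects one. A barcode yields a pair only if both loci survive.
    """
    by_barcode: dict[str, dict[str, list[ChainRecord]]] = defaultdict(lambda: {"TRA": [], "TRB": []})
    for rec in records:
        if rec.productive:
            by_barcode[rec.barcode][rec.locus].append(rec)
        else:
            by_barcode[rec.barcode]  # register the barcode even if nothing survives
    out: dict[str, PairedTcr | None] = {}
    for bc, loci in by_barcode.items():
        if loci["TRA"] and loci["TRB"]:
            out[bc] = PairedTcr(barcode=bc, alpha=_best_chain(loci["TRA"]), beta=_best_chain(loci["TRB"]))
        else:
            out[bc] = None
    return out


def clonotype_key(pair: PairedTcr, mode: str = "cdr3nt_vj") -> tuple:
    """Grouping key for clonotype assembly.

    ``cdr3nt_vj`` (default): CDR3 nucleotide sequences plus V/(D)/J segment
    names of both chains. ``cdr3nt_only``: the nucleotide sequences alone.
    """
    if mode == "cdr3nt_vj":
        return (
            pair.alpha.cdr3_nt, pair.alpha.v_gene, pair.alpha.j_gene,
            pair.beta.cdr3_nt, pair.beta.v_gene, pair.beta.d_gene, pair.beta.j_gene,
        )
    if mode == "cdr3nt_only":
        return (pair.alpha.cdr3_nt, pair.beta.cdr3_nt)
    raise ValueError(f"unknown clonotype key mode {mode!r}")


def _clonotype_id(key: tuple) -> str:
    digest = hashlib.sha1("|".join(key).encode()).hexdigest()[:12]
    return f"ct-{digest}"


def build_clonotypes(
    pairs: list[PairedTcr], key_mode: str = "cdr3nt_vj"
) -> tuple[list[Clonotype], dict[str, str]]:
    """Group paired cells into clonotypes; returns (clonotypes, barcode map).

    Annotations (V/J calls, CDR3 amino-acid sequences) are copied from the
    member with the lexicographically smallest barcode, so assembly is
    deterministic under input permutation. Clonotypes are returned in
    descending size order, ties by clonotype_id.
    """
    seen: set[str] = set()
    groups: dict[tuple, list[PairedTcr]] = defaultdict(list)
    for p in pairs:
        if p.barcode in seen:
            raise ValueError(f"duplicate barcode in paired input: {p.barcode}")
        seen.add(p.barcode)
        groups[clonotype_key(p, key_mode)].append(p)

    clonotypes: list[Clonotype] = []
    barcode_map: dict[str, str] = {}
    for key, members in groups.items():
        cid = _clonotype_id(key)
        rep = min(members, key=lambda p: p.barcode)
        ct = Clonotype(
            clonotype_id=cid,
            alpha_nt=rep.alpha.cdr3_nt,
            beta_nt=rep.beta.cdr3_nt,
            trav=rep.alpha.v_gene,
            traj=rep.alpha.j_gene,
            trbv=rep.beta.v_gene,
            trbd=rep.beta.d_gene,
            trbj=rep.beta.j_gene,
            cdr3_alpha_aa=rep.alpha.cdr3_aa,
            cdr3_beta_aa=rep.beta.cdr3_aa,
            member_barcodes={p.barcode for p in members},
        )
        clonotypes.append(ct)
        for p in members:
            barcode_map[p.barcode] = cid
    clonotypes.sort(key=lambda c: (-c.n_cells, c.clonotype_id))
    return clonotypes, barcode_map


def intersect_modalities(expression_kept: set[str], paired: set[str]) -> set[str]:
    """Final analysis cells: expression-QC-passing AND productively paired."""
    final = set(expression_kept) & set(paired)
    logger.info(
        "joint QC: %d expression-kept, %d paired, %d in intersection",
        len(expression_kept), len(paired), len(final),
    )
    if not final:
        logger.warning("empty intersection of expression and TCR modalities")
    return final


def clonotype_table(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Clonotype annotations as a DataFrame with report-style columns."""
    return pd.DataFrame(
        {
            "clonotype_id": [c.clonotype_id for c in clonotypes],
            "n_cells": [c.n_cells for c in clonotypes],
            "TRAV": [c.trav for c in clonotypes],
            "TRAJ": [c.traj for c in clonotypes],
            "CDR3_alpha": [c.cdr3_alpha_aa for c in clonotypes],
            "TRBV": [c.trbv for c in clonotypes],
            "TRBD": [c.trbd for c in clonotypes],
            "TRBJ": [c.trbj for c in clonotypes],
            "CDR3_beta": [c.cdr3_beta_aa for c in clonotypes],
        }
    )
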