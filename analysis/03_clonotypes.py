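"""Clonotype the example dataset's V(D)J contigs.

Resolves one productive alpha+beta pair per cell (UMI/read tie cascade for
multi-chain cells), groups cells into nucleotide clonotypes, and intersects
the paired cells with the expression-QC survivors. Writes the clonotype
table and the barcode-to-clonotype map under results/tcr/.
"""

from pathlib import Path

import pandas as pd

from tcrscreen import build_clonotypes, intersect_modalities, parse_contigs, resolve_paired_tcr
from tcrscreen.tcr import clonotype_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_contigs((ROOT / "sim" / "contigs.csv").read_text())
    pairs_by_bc = resolve_paired_tcr(records)
    pairs = [p for p in pairs_by_bc.values() if p is not None]
    clonotypes, bc_map = build_clonotypes(pairs)
    kept = set((ROOT / "qc" / "kept_barcodes.txt").read_text().split())
    final = intersect_modalities(kept, set(bc_map))

    out = ROOT / "tcr"
    out.mkdir(parents=True, exist_ok=True)
    clonotype_table(clonotypes).to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    pd.Series(bc_map, name="clonotype_id").rename_axis("barcode").to_csv(
        out / "barcode_clonotypes.tsv", sep="\t")
    (out / "final_barcodes.txt").write_text("".join(b + "\n" for b in sorted(final)))
    expanded = sum(1 for c in clonotypes if c.n_cells >= 2)
    print(f"{len(pairs)} paired cells in {len(clonotypes)} clonotypes "
          f"({expanded} expanded >=2 cells); joint-QC cells: {len(final)}")


if __name__ == "__main__":
    main()
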