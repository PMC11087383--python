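"""Expression QC of the example dataset.

Applies the three-criterion cell gate (800-10,000 detected genes,
mitochondrial fraction < 0.2, mean CD3D/E/G UMI > 0) and reports how many
cells each criterion removes. Writes the kept-barcode list and a JSON
report under results/qc/.
"""

from pathlib import Path

from tcrscreen import QcThresholds, compute_cell_qc, filter_cells, read_counts_10x

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_counts_10x(ROOT / "sim" / "matrix")
    thr = QcThresholds()
    metrics = compute_cell_qc(counts, thr)
    kept, report = filter_cells(metrics, thr)
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    (out / "qc_report.json").write_text(report.to_json() + "\n")
    (out / "kept_barcodes.txt").write_text(
        "".join(b + "\n" for b in counts.barcodes if b in kept))
    print(f"kept {report.n_kept}/{report.n_total} cells "
          f"(low genes: {report.fail_low_genes}, high genes: {report.fail_high_genes}, "
          f"mito: {report.fail_mito}, CD3: {report.fail_cd3})")


if __name__ == "__main__":
    main()
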