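"""Binned-control module scoring: oracle equivalence and analytic limits."""

import numpy as np
import pytest

from tcrscreen.matrix import NormMatrix
from tcrscreen.qc import log_normalize
from tcrscreen.scoring import (
    DETERMINISTIC_FULL_BIN,
    ModuleScoreParams,
    bin_genes_by_mean_expression,
    compute_module_score,
    gene_expression,
    sample_control_genes,
)

from conftest import make_counts, random_norm_matrix


def brute_force_score(norm: NormMatrix, signature, n_bins) -> np.ndarray:
    """Independent oracle: mean(signature) - mean(union of whole bins).

    Re-derives the deterministic binned-control score with plain dense
    numpy: rank genes by mean value (ties by symbol), cut the ranking into
    n_bins contiguous chunks whose sizes differ by at most one (larger
    chunks first), and pool the entire bin of each signature gene with
    multiplicity.
    """
    dense = np.asarray(norm.values.todense())
    means = dense.mean(axis=1)
    order = sorted(range(len(norm.genes)), key=lambda i: (means[i], norm.genes[i]))
    n, b = len(order), n_bins
    sizes = [n // b + 1] * (n % b) + [n // b] * (b - n % b)
    bins, start = [], 0
    for s in sizes:
        bins.append(order[start:start + s])
        start += s
    gi = {g: i for i, g in enumerate(norm.genes)}
    ctrl_rows = []
    for g in signature:
        row = gi[g]
        ctrl_rows.extend(next(bn for bn in bins if row in bn))
    sig_rows = [gi[g] for g in signature]
    return dense[sig_rows].mean(axis=0) - dense[ctrl_rows].mean(axis=0)


class TestBinning:
    def test_equal_frequency_two_bins(self):
        norm = log_normalize(make_counts([[1, 1], [10, 10], [2, 2], [20, 20]],
                                         genes=["a", "b", "c", "d"]))
        bins = bin_genes_by_mean_expression(norm, 2)
        assert bins["a"] == bins["c"] == 0  # lowest-mean pair in the first bin
        assert bins["b"] == bins["d"] == 1

    def test_ties_resolved_by_symbol(self):
        norm = log_normalize(make_counts(np.ones((4, 2), dtype=int),
                                         genes=["d", "c", "b", "a"]))
        bins = bin_genes_by_mean_expression(norm, 2)
        assert bins == {"a": 0, "b": 0, "c": 1, "d": 1}

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        norm = random_norm_matrix(rng, n_genes=25, n_cells=4)
        bins = bin_genes_by_mean_expression(norm, 24)
        sizes = np.bincount(list(bins.values()), minlength=24)
        assert sorted(sizes.tolist()) == [1] * 23 + [2]

    def test_more_bins_than_genes_errors(self):
        rng = np.random.default_rng(0)
        norm = random_norm_matrix(rng, n_genes=5, n_cells=3)
        with pytest.raises(ValueError, match="n_bins"):
            bin_genes_by_mean_expression(norm, 6)


class TestControlSampling:
    def _bins(self, n_genes=20, n_bins=4):
        return {f"G{i}": i % n_bins for i in range(n_genes)}

    def test_same_seed_reproducible(self):
        bins = self._bins()
        a = sample_control_genes(bins, ["G0", "G1"], n_ctrl=3, seed=42)
        b = sample_control_genes(bins, ["G0", "G1"], n_ctrl=3, seed=42)
        assert a == b

    def test_exhaustive_draw_equals_full_bin(self):
        bins = self._bins()
        stoch = sample_control_genes(bins, ["G0"], n_ctrl=100, seed=0)
        det = sample_control_genes(bins, ["G0"], mode=DETERMINISTIC_FULL_BIN)
        assert sorted(stoch) == sorted(det)

    def test_multiset_size_counts(self):
        bins = {f"G{i}": i // 5 for i in range(50)}  # ten bins of five
        sig = [f"G{i * 5}" for i in range(10)]
        controls = sample_control_genes(bins, sig, n_ctrl=3, seed=0)
        assert len(controls) == 30


class TestModuleScore:
    def test_deterministic_mode_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            norm = random_norm_matrix(rng)
            n_sig = int(rng.integers(1, min(6, norm.n_genes) + 1))
            sig = list(rng.choice(norm.genes, size=n_sig, replace=False))
            n_bins = int(rng.integers(1, norm.n_genes + 1))
            got = compute_module_score(
                norm, sig, ModuleScoreParams(n_bins=n_bins, mode=DETERMINISTIC_FULL_BIN))
            expected = brute_force_score(norm, sig, n_bins)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_uniform_matrix_scores_zero_and_shifts_cancel(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_genes, n_cells = int(rng.integers(6, 30)), int(rng.integers(2, 10))
            genes = [f"G{i}" for i in range(n_genes)]
            bcs = [f"B{j}" for j in range(n_cells)]
            percell = rng.uniform(0.5, 3.0, size=n_cells)
            vals = np.tile(percell, (n_genes, 1))  # all genes equal within a cell
            norm = NormMatrix(genes=genes, barcodes=bcs, values=vals)
            sig = list(rng.choice(genes, size=3, replace=False))
            params = ModuleScoreParams(n_bins=int(rng.integers(1, 5)),
                                       mode=DETERMINISTIC_FULL_BIN)
            np.testing.assert_allclose(
                compute_module_score(norm, sig, params), 0.0, atol=1e-12)
            # adding a per-cell constant to every gene leaves scores unchanged
            base = rng.uniform(0, 2, size=(n_genes, n_cells))
            shifted = base + rng.uniform(0, 5, size=n_cells)[None, :]
            s0 = compute_module_score(
                NormMatrix(genes=genes, barcodes=bcs, values=base), sig, params)
            s1 = compute_module_score(
                NormMatrix(genes=genes, barcodes=bcs, values=shifted), sig, params)
            np.testing.assert_allclose(s0, s1, atol=1e-10)

    def test_single_gene_signature_closed_form(self):
        # one expressed gene in a bin of m otherwise all-zero genes:
        # score = value * (1 - 1/m) in deterministic mode
        vals = np.zeros((6, 3))
        vals[0] = [0.5, 1.0, 2.0]
        genes = [f"G{i}" for i in range(6)]
        norm = NormMatrix(genes=genes, barcodes=["a", "b", "c"], values=vals)
        got = compute_module_score(norm, ["G0"],
                                   ModuleScoreParams(n_bins=1, mode=DETERMINISTIC_FULL_BIN))
        np.testing.assert_allclose(got, vals[0] * (1 - 1 / 6), atol=1e-12)
        np.testing.assert_allclose(got, brute_force_score(norm, ["G0"], 1), atol=1e-12)

    def test_stochastic_mode_seed_reproducible(self):
        rng = np.random.default_rng(3)
        norm = random_norm_matrix(rng, n_genes=40, n_cells=10)
        params = ModuleScoreParams(n_bins=4, n_ctrl=5, seed=11)
        a = compute_module_score(norm, norm.genes[:3], params)
        b = compute_module_score(norm, norm.genes[:3], params)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_stochastic_converges_to_deterministic_when_ctrl_exhausts_bins(self):
        rng = np.random.default_rng(4)
        norm = random_norm_matrix(rng, n_genes=20, n_cells=8)
        sig = norm.genes[:2]
        stoch = compute_module_score(norm, sig, ModuleScoreParams(n_bins=4, n_ctrl=100, seed=5))
        det = compute_module_score(norm, sig,
                                   ModuleScoreParams(n_bins=4, mode=DETERMINISTIC_FULL_BIN))
        np.testing.assert_allclose(stoch, det, atol=1e-12)

    def test_gene_cell_permutation_invariance(self):
        rng = np.random.default_rng(5)
        norm = random_norm_matrix(rng, n_genes=15, n_cells=6)
        sig = [norm.genes[2], norm.genes[9]]
        params = ModuleScoreParams(n_bins=3, mode=DETERMINISTIC_FULL_BIN)
        ref = compute_module_score(norm, sig, params)
        gperm = rng.permutation(norm.n_genes)
        cperm = rng.permutation(norm.n_cells)
        permuted = NormMatrix(
            genes=[norm.genes[i] for i in gperm],
            barcodes=[norm.barcodes[j] for j in cperm],
            values=norm.values[gperm][:, cperm],
        )
        got = compute_module_score(permuted, sig, params)
        np.testing.assert_allclose(got, ref[cperm], atol=1e-12)

    def test_missing_signature_gene_listed_in_error(self):
        rng = np.random.default_rng(6)
        norm = random_norm_matrix(rng, n_genes=10, n_cells=4)
        with pytest.raises(ValueError, match="NOPE"):
            compute_module_score(norm, ["NOPE", norm.genes[0]])


class TestGeneExpression:
    def test_matches_normalized_row(self):
        cm = make_counts([[1, 0], [3, 2]], genes=["IFNG", "ACTB"])
        norm = log_normalize(cm)
        np.testing.assert_allclose(gene_expression(norm, "IFNG"),
                                   np.asarray(norm.values.todense())[0])

    def test_zero_count_gene_is_all_zero(self):
        cm = make_counts([[0, 0], [3, 2]], genes=["IFNG", "ACTB"])
        assert (gene_expression(log_normalize(cm), "IFNG") == 0).all()

    def test_unknown_symbol_suggests_nearest(self):
        cm = make_counts([[1], [3]], genes=["IFNG", "ACTB"])
        with pytest.raises(KeyError, match="IFNG"):
            gene_expression(log_normalize(cm), "IFNg")
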