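"""Clonotype aggregation, ranking order, and candidate-panel selection."""

import numpy as np
import pandas as pd
import pytest

from tcrscreen.ranking import (
    aggregate_by_clonotype,
    rank_clonotypes,
    select_candidate_panel,
)


class TestAggregate:
    def test_arithmetic_mean_and_size_filter(self):
        values = {"a": 0.5, "b": 0.7, "c": 0.9, "d": 1.0, "e": 2.0}
        bc_map = {"a": "ct1", "b": "ct1", "c": "ct1", "d": "ct2", "e": "ct2"}
        ranking_tbl, full = aggregate_by_clonotype(values, bc_map, min_cells=3)
        assert ranking_tbl["clonotype_id"].tolist() == ["ct1"]
        assert ranking_tbl["mean"].iloc[0] == pytest.approx(0.7)
        # the 2-cell clonotype stays in the full table only
        assert set(full["clonotype_id"]) == {"ct1", "ct2"}

    def test_cell_conservation_in_full_table(self):
        rng = np.random.default_rng(0)
        bcs = [f"b{i}" for i in range(50)]
        bc_map = {b: f"ct{rng.integers(8)}" for b in bcs}
        values = {b: float(rng.normal()) for b in bcs}
        _, full = aggregate_by_clonotype(values, bc_map, min_cells=3)
        assert full["n_cells"].sum() == 50

    def test_unmapped_barcodes_dropped_not_fatal(self):
        tbl, full = aggregate_by_clonotype(
            {"a": 1.0, "zz": 5.0}, {"a": "ct1"}, min_cells=1)
        assert full["n_cells"].sum() == 1

    def test_single_clonotype_mean_is_global_mean(self):
        values = {"a": 1.0, "b": 2.0, "c": 6.0}
        tbl, _ = aggregate_by_clonotype(values, {b: "ct" for b in values}, min_cells=3)
        assert tbl["mean"].iloc[0] == pytest.approx(3.0)

    def test_fully_disjoint_inputs_error(self):
        with pytest.raises(ValueError):
            aggregate_by_clonotype({"a": 1.0}, {"b": "ct1"})


def table(rows):
    return pd.DataFrame(rows, columns=["clonotype_id", "mean", "n_cells"])


class TestRank:
    def test_descending_with_size_then_id_ties(self):
        t = table([("x", 0.9, 3), ("y", 0.9, 5), ("z", 1.5, 2)])
        ranked = rank_clonotypes(t, "IFNG")
        assert ranked["clonotype_id"].tolist() == ["z", "y", "x"]
        assert ranked["rank"].tolist() == [1, 2, 3]
        tie = rank_clonotypes(table([("b", 1.0, 3), ("a", 1.0, 3)]), "IFNG")
        assert tie["clonotype_id"].tolist() == ["a", "b"]

    def test_permutation_invariance_and_rerank_identity(self):
        rng = np.random.default_rng(1)
        t = table([(f"ct{i}", float(rng.choice([0.1, 0.5, 0.5, 2.0])),
                    int(rng.integers(3, 9))) for i in range(20)])
        ref = rank_clonotypes(t, "SCORE")
        for _ in range(5):
            shuffled = t.sample(frac=1, random_state=int(rng.integers(1000)))
            got = rank_clonotypes(shuffled, "SCORE")
            assert got["clonotype_id"].tolist() == ref["clonotype_id"].tolist()
        again = rank_clonotypes(ref[["clonotype_id", "mean", "n_cells"]], "SCORE")
        assert again["clonotype_id"].tolist() == ref["clonotype_id"].tolist()

    def test_scaling_values_preserves_ranks(self):
        rng = np.random.default_rng(2)
        t = table([(f"ct{i}", float(rng.uniform(0.1, 2)), int(rng.integers(3, 9)))
                   for i in range(15)])
        ref = rank_clonotypes(t, "SCORE")["clonotype_id"].tolist()
        scaled = t.assign(mean=t["mean"] * 17.5)
        assert rank_clonotypes(scaled, "SCORE")["clonotype_id"].tolist() == ref

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            rank_clonotypes(table([]), "IFNG")

    def test_single_row_ranks_first(self):
        ranked = rank_clonotypes(table([("only", 0.2, 4)]), "TNFRSF9")
        assert ranked["rank"].tolist() == [1]


def ranked_fixture(ids):
    t = table([(cid, 1.0 - 0.1 * i, 5) for i, cid in enumerate(ids)])
    return rank_clonotypes(t, "IFNG").assign(key="IFNG")


class TestPanel:
    def test_disjoint_keys_give_three_k_entries(self):
        ranked = {
            "IFNG": ranked_fixture(["a", "b", "c"]),
            "TNFRSF9": ranked_fixture(["d", "e", "f"]),
            "SCORE": ranked_fixture(["g", "h", "i"]),
        }
        panel = select_candidate_panel(ranked, k=3)
        assert len(panel.entries) == 9

    def test_identical_keys_collapse_to_k(self):
        one = ranked_fixture(["a", "b", "c", "d"])
        panel = select_candidate_panel({"IFNG": one, "TNFRSF9": one, "SCORE": one}, k=3)
        assert len(panel.entries) == 3
        assert all(e.selected_by == {"IFNG", "TNFRSF9", "SCORE"} for e in panel.entries)

    def test_partial_overlap_union_of_labels(self):
        panel = select_candidate_panel(
            {"IFNG": ranked_fixture(["a", "b", "c"]),
             "TNFRSF9": ranked_fixture(["a", "d", "e"])}, k=3)
        assert len(panel.entries) == 5
        byid = {e.clonotype_id: e for e in panel.entries}
        assert byid["a"].selected_by == {"IFNG", "TNFRSF9"}

    def test_small_table_takes_all_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="tcrscreen.ranking"):
            panel = select_candidate_panel({"IFNG": ranked_fixture(["a", "b"])}, k=3)
        assert len(panel.entries) == 2
        assert any("exceeds" in r.message for r in caplog.records)

    def test_entries_ordered_by_best_rank(self):
        panel = select_candidate_panel(
            {"IFNG": ranked_fixture(["a", "b", "c"]),
             "SCORE": ranked_fixture(["c", "d", "e"])}, k=2)
        # a (rank 1 IFNG) and c (rank 1 SCORE) tie on best rank -> id order
        assert panel.clonotype_ids()[:2] == ["a", "c"]


class TestPublishedWorkedExample:
    @pytest.mark.parametrize("patient", ["P1", "P2"])
    def test_six_single_marker_selections_collapse_to_five(self, patient):
        from tcrscreen.published import published_panel
        panel = published_panel(patient, groups=("IFN", "41BB"), k=3)
        assert len(panel.entries) == 5
        # the shared entry is the clonotype topping both single-marker lists
        shared = [e for e in panel.entries if len(e.selected_by) == 2]
        assert len(shared) == 1
        assert shared[0].ranks == {"IFNG": 1, "TNFRSF9": 1}
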