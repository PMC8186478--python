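"""Tumor application: cluster filtering, stem-like logic, enrichment,
consensus signatures."""

import numpy as np
import pandas as pd
import pytest

from cycleclass import (
    CountMatrix,
    MarkerPanel,
    StemLogicConfig,
    consensus_markers,
    filter_neoplastic_clusters,
    find_markers,
    overlap_enrichment,
    stem_like_mask,
)
from cycleclass.errors import ParameterError, ValidationError
from conftest import make_norm

STEM_GENES = ["FUT4", "L1CAM", "PROM1", "SOX2", "TLR4"]


def _counts(values, gene_ids):
    values = np.asarray(values)
    return CountMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=[f"c{j}" for j in range(values.shape[1])],
    )


class TestStemLikeMask:
    def test_all_zero_cell_is_false(self):
        cm = _counts(np.zeros((5, 3), dtype=int), STEM_GENES)
        assert not stem_like_mask(cm).any()

    def test_direct_logic(self):
        # columns: stem-like; same but TLR4+; missing SOX2; PROM1 only
        vals = np.array(
            [
                [0, 0, 0, 0],  # FUT4
                [0, 0, 0, 0],  # L1CAM
                [3, 3, 3, 3],  # PROM1
                [1, 1, 0, 0],  # SOX2
                [0, 1, 0, 0],  # TLR4
            ]
        )
        mask = stem_like_mask(_counts(vals, STEM_GENES))
        np.testing.assert_array_equal(mask, [True, False, False, False])

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        genes = STEM_GENES + [f"other{i}" for i in range(5)]
        vals = rng.integers(0, 3, size=(len(genes), 200))
        cm = _counts(vals, genes)
        mask = stem_like_mask(cm)
        g = {name: i for i, name in enumerate(genes)}
        for j in range(cm.n_cells):
            col = vals[:, j]
            expected = (
                (col[g["FUT4"]] > 0 or col[g["L1CAM"]] > 0 or col[g["PROM1"]] > 0)
                and col[g["SOX2"]] > 0
                and col[g["TLR4"]] == 0
            )
            assert mask[j] == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        genes = STEM_GENES + ["x"]
        vals = rng.integers(0, 2, size=(6, 50))
        cm = _counts(vals, genes)
        perm = rng.permutation(50)
        cm_perm = CountMatrix(
            values=vals[:, perm],
            gene_ids=genes,
            cell_ids=[cm.cell_ids[i] for i in perm],
        )
        np.testing.assert_array_equal(stem_like_mask(cm)[perm], stem_like_mask(cm_perm))

    def test_missing_required_gene_is_hard_error(self):
        cm = _counts(np.zeros((4, 2), dtype=int), ["FUT4", "L1CAM", "PROM1", "TLR4"])
        with pytest.raises(ValidationError, match="SOX2"):
            stem_like_mask(cm)

    def test_overlapping_logic_sets_rejected(self):
        with pytest.raises(ValidationError):
            StemLogicConfig(any_of={"SOX2", "PROM1"})


class TestClusterFilter:
    def _norm_with_clusters(self, n_clusters=8, cells_per=10, mbp_cluster=0):
        rng = np.random.default_rng(3)
        genes = ["MBP", "PLP1", "ETNPPL", "RBFOX3", "AIF1", "CD14", "CX3CR1",
                 "PTPRC", "other1", "other2"]
        n = n_clusters * cells_per
        # panel genes silent everywhere; non-panel genes carry noise
        vals = np.zeros((len(genes), n))
        vals[8:, :] = rng.normal(0.5, 0.1, size=(2, n)).clip(min=0)
        y = np.repeat([f"cl{i}" for i in range(n_clusters)], cells_per)
        if mbp_cluster is not None:
            vals[0, y == f"cl{mbp_cluster}"] = 10.0
        return make_norm(vals, gene_ids=genes), y

    def test_mbp_high_cluster_excluded_with_trigger(self):
        norm, y = self._norm_with_clusters(mbp_cluster=0)
        retained, report = filter_neoplastic_clusters(norm, y)
        assert list(report["cluster"]) == ["cl0"]
        assert report["trigger_gene"].iloc[0] == "MBP"
        assert report["lineage"].iloc[0] == "oligodendrocyte"
        kept_clusters = {c for c, cid in zip(y, norm.cell_ids) if cid in retained}
        assert "cl0" not in kept_clusters and len(kept_clusters) == 7

    def test_no_panel_expression_retains_everything(self):
        norm, y = self._norm_with_clusters(mbp_cluster=None)
        rng = np.random.default_rng(0)
        quiet = make_norm(np.zeros_like(norm.values), gene_ids=list(norm.gene_ids))
        retained, report = filter_neoplastic_clusters(quiet, y)
        assert len(retained) == quiet.n_cells
        assert report.empty

    def test_absent_panel_gene_warns_and_skips(self):
        norm, y = self._norm_with_clusters(mbp_cluster=None)
        sub = make_norm(norm.values[8:], gene_ids=list(norm.gene_ids[8:]))
        with pytest.warns(UserWarning):
            retained, report = filter_neoplastic_clusters(sub, y)
        assert len(retained) == sub.n_cells

    def test_default_panel_content(self):
        panel = MarkerPanel()
        assert panel.lineages["immune"] == {"AIF1", "CD14", "CX3CR1", "PTPRC"}
        assert panel.lineages["oligodendrocyte"] == {"MBP", "PLP1"}
        assert panel.lineages["astrocyte"] == {"ETNPPL"}
        assert panel.lineages["neuron"] == {"RBFOX3"}

    def test_single_cluster_rejected(self):
        norm, _ = self._norm_with_clusters()
        with pytest.raises(ValidationError):
            filter_neoplastic_clusters(norm, ["only"] * norm.n_cells)


class TestOverlapEnrichment:
    def test_worked_value(self):
        universe = set(range(10))
        res = overlap_enrichment(universe, set(range(5)), {0, 1, 2, 3})
        assert res.p_value == pytest.approx(5 / 210)

    def test_disjoint_sets_p_one(self):
        res = overlap_enrichment(set(range(10)), {0, 1}, {5, 6})
        assert res.overlap == 0
        assert res.p_value == 1.0

    def test_full_overlap_edge_case(self):
        u = set(range(6))
        res = overlap_enrichment(u, u, u)
        assert res.p_value == 1.0

    def test_non_subset_rejected(self):
        with pytest.raises(ParameterError):
            overlap_enrichment({1, 2}, {1, 3}, {2})

    def test_enrichment_minimized_at_true_phase(self, small_sim):
        # plant a "stem" subpopulation inside Neural G0
        rng = np.random.default_rng(9)
        y = small_sim.true_labels.labels
        cells = np.array(small_sim.counts.cell_ids)
        g0 = cells[y == "Neural G0"]
        others = cells[y != "Neural G0"]
        stem = set(rng.choice(g0, size=40, replace=False)) | set(
            rng.choice(others, size=8, replace=False)
        )
        universe = set(cells)
        pvals = {
            phase: overlap_enrichment(universe, set(cells[y == phase]), stem).p_value
            for phase in set(y)
        }
        assert min(pvals, key=pvals.get) == "Neural G0"


class TestConsensusMarkers:
    def _table(self, phase, marker_genes, extra_rows=()):
        rows = [
            {"cluster": phase, "gene": g, "avg_logFC": 1.0, "p": 1e-5,
             "p_adj": 1e-4, "is_marker": True}
            for g in marker_genes
        ]
        rows += list(extra_rows)
        return pd.DataFrame(rows)

    def test_single_table_identity(self):
        t = self._table("G0", ["a", "b"])
        assert consensus_markers([t], "G0") == ["a", "b"]

    def test_disjoint_tables_empty(self):
        t1 = self._table("G0", ["a"])
        t2 = self._table("G0", ["b"])
        assert consensus_markers([t1, t2], "G0") == []

    def test_size_non_increasing_with_more_tables(self):
        tables = [
            self._table("G0", genes)
            for genes in (["a", "b", "c"], ["a", "b"], ["a", "x"])
        ]
        sizes = [
            len(consensus_markers(tables[: i + 1], "G0")) for i in range(3)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_missing_phase_names_table(self):
        t = self._table("G0", ["a"])
        with pytest.raises(ParameterError, match="#0"):
            consensus_markers([t], "S")

    def test_four_simulated_datasets_recover_planted_shared_set(self):
        # four datasets share a common planted marker set for phase "A";
        # each also has private markers, which must not survive intersection
        rng = np.random.default_rng(5)
        common = [f"shared{i}" for i in range(10)]
        tables = []
        for d in range(4):
            private = [f"ds{d}_own{i}" for i in range(5)]
            genes = common + private + [f"noise{i}" for i in range(40)]
            n_a, n_b = 30, 60
            vals = rng.normal(1.0, 0.1, size=(len(genes), n_a + n_b))
            for g in common + private:
                vals[genes.index(g), :n_a] += 1.0
            y = np.array(["A"] * n_a + ["B"] * n_b)
            tables.append(find_markers(make_norm(vals, gene_ids=genes), y))
        assert consensus_markers(tables, "A") == sorted(common)
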