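"""Selection, export, violin and heatmap against brute-force oracles."""

import numpy as np
import pytest

import cellbundle as cb
from cellbundle.annotate import type_table
from cellbundle.matrix_store import build_store
from cellbundle.query import (GroupStats, Predicate, QueryError,
                              SelectionQuery, cluster_means, export_cells,
                              parse_predicate, select_cells, violin_stats)


@pytest.fixture(scope="module")
def typed(dataset):
    matrix, cells, layouts, genes, truth = dataset
    return type_table(cells)


@pytest.fixture(scope="module")
def store(dataset, tmp_path_factory):
    return build_store(dataset[0], tmp_path_factory.mktemp("store"))


def brute_force_select(cells, q: SelectionQuery) -> set:
    """Independent oracle: evaluate every predicate on every raw row."""
    out = set()
    for i, cell in enumerate(cells.cell_ids):
        ok = True
        for p in q.predicates:
            raw = cells.columns[p.field][i]
            if p.op == "equals":
                ok &= raw == str(p.operand)
            elif p.op == "in":
                ok &= raw in {str(v) for v in p.operand}
            elif p.op == "range":
                ok &= p.operand[0] <= float(raw) <= p.operand[1]
            elif p.op == "gt":
                ok &= float(raw) > float(p.operand)
            elif p.op == "lt":
                ok &= float(raw) < float(p.operand)
            if not ok:
                break
        if ok:
            out.add(cell)
    return out


class TestSelect:
    def test_single_categorical_predicate(self, dataset, typed):
        _, cells, *_ = dataset
        label = cells.columns["cluster"][0]
        q = SelectionQuery([Predicate("cluster", "equals", label)])
        got = select_cells(typed, cells.cell_ids, q)
        assert got == {c for c, v in zip(cells.cell_ids,
                                         cells.columns["cluster"])
                       if v == label}

    def test_empty_predicate_list_selects_all(self, dataset, typed):
        _, cells, *_ = dataset
        assert len(select_cells(typed, cells.cell_ids, SelectionQuery())) \
            == cells.n_cells

    def test_unknown_field_lists_names(self, dataset, typed):
        _, cells, *_ = dataset
        with pytest.raises(QueryError, match="cluster"):
            select_cells(typed, cells.cell_ids,
                         SelectionQuery([Predicate("nope", "equals", "x")]))

    def test_range_on_categorical_is_type_error(self, dataset, typed):
        _, cells, *_ = dataset
        with pytest.raises(QueryError, match="categorical"):
            select_cells(typed, cells.cell_ids,
                         SelectionQuery([Predicate("cluster", "range",
                                                   (0, 1))]))

    def test_range_is_closed(self, dataset, typed):
        _, cells, *_ = dataset
        ages = np.array([float(a) for a in cells.columns["age"]])
        lo, hi = sorted(set(ages))[1], sorted(set(ages))[-2]
        q = SelectionQuery([Predicate("age", "range", (lo, hi))])
        got = select_cells(typed, cells.cell_ids, q)
        assert len(got) == int(((ages >= lo) & (ages <= hi)).sum())

    def test_hundred_random_queries_match_brute_force(self, dataset, typed):
        """Property check: 100 seeded random conjunctions scan-identical."""
        _, cells, *_ = dataset
        rng = np.random.default_rng(123)
        clusters = sorted(set(cells.columns["cluster"]))
        for _ in range(100):
            preds = []
            if rng.random() < 0.8:
                preds.append(Predicate("cluster",
                                       "in" if rng.random() < 0.5 else "equals",
                                       list(rng.choice(clusters, size=2))
                                       if rng.random() < 0.5
                                       else str(rng.choice(clusters))))
            if rng.random() < 0.8:
                lo, hi = sorted(rng.integers(20, 71, size=2).tolist())
                preds.append(Predicate("age", "range", (lo, hi)))
            if rng.random() < 0.3:
                preds.append(Predicate("age", "gt",
                                       int(rng.integers(20, 71))))
            q = SelectionQuery(preds)
            assert select_cells(typed, cells.cell_ids, q) \
                == brute_force_select(cells, q)

    def test_parse_predicate_forms(self):
        assert parse_predicate("cluster=RG-div1").op == "equals"
        assert parse_predicate("cluster=a,b").op == "in"
        assert parse_predicate("age=30..40").operand == (30.0, 40.0)
        assert parse_predicate("age>35").op == "gt"
        assert parse_predicate("age<35").op == "lt"


class TestExport:
    def test_empty_selection_writes_empty_file(self, tmp_path):
        n = export_cells(set(), ["c1", "c2"], tmp_path / "out.txt")
        assert n == 0 and (tmp_path / "out.txt").read_text() == ""

    def test_all_cells_in_canonical_order(self, dataset, tmp_path):
        _, cells, *_ = dataset
        n = export_cells(set(cells.cell_ids), cells.cell_ids,
                         tmp_path / "out.txt")
        assert n == cells.n_cells
        lines = (tmp_path / "out.txt").read_text().splitlines()
        assert lines == cells.cell_ids

    def test_round_trip_reproduces_selection(self, dataset, tmp_path):
        _, cells, *_ = dataset
        rng = np.random.default_rng(7)
        sel = set(rng.choice(cells.cell_ids, size=37, replace=False).tolist())
        export_cells(sel, cells.cell_ids, tmp_path / "out.txt")
        assert set((tmp_path / "out.txt").read_text().splitlines()) == sel


class TestViolin:
    def test_two_group_means(self, tmp_path):
        m = cb.ExpressionMatrix(["g"], ["c1", "c2", "c3", "c4"],
                                [[0, 0, 10, 10]])
        store = build_store(m, tmp_path)
        comp = violin_stats(store, "g", {"c3", "c4"}, m.cell_ids)
        assert comp.group_a.mean == 10 and comp.group_b.mean == 0

    def test_selection_covering_all_cells_is_error(self, tmp_path):
        m = cb.ExpressionMatrix(["g"], ["c1", "c2"], [[1, 2]])
        store = build_store(m, tmp_path)
        with pytest.raises(QueryError, match="empty"):
            violin_stats(store, "g", {"c1", "c2"}, m.cell_ids)

    def test_background_overlap_removed_and_counted(self, tmp_path):
        m = cb.ExpressionMatrix(["g"], ["c1", "c2", "c3"], [[1, 2, 3]])
        store = build_store(m, tmp_path)
        comp = violin_stats(store, "g", {"c1"}, m.cell_ids,
                            background={"c1", "c3"})
        assert comp.background_overlap_removed == 1
        assert comp.group_b.cell_count == 1

    def test_stats_match_dense_recomputation(self, dataset, store):
        matrix, cells, *_ = dataset
        rng = np.random.default_rng(21)
        sel = set(rng.choice(cells.cell_ids, size=100, replace=False).tolist())
        gene = matrix.gene_ids[11]
        comp = violin_stats(store, gene, sel, cells.cell_ids)
        row = matrix.values[11].astype(np.float64)
        mask = np.array([c in sel for c in cells.cell_ids])
        for group, values in ((comp.group_a, row[mask]),
                              (comp.group_b, row[~mask])):
            assert group.cell_count == values.size
            assert group.mean == pytest.approx(values.mean(), abs=1e-9)
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            assert (group.q1, group.median, group.q3) == \
                pytest.approx((q1, med, q3), abs=1e-9)

    def test_weighted_group_means_reconstruct_global_mean(self, dataset,
                                                          store):
        """Conservation: n_a*mean_a + n_b*mean_b == n*global_mean."""
        matrix, cells, *_ = dataset
        gene = matrix.gene_ids[3]
        sel = set(cells.cell_ids[:250])
        comp = violin_stats(store, gene, sel, cells.cell_ids)
        total = (comp.group_a.cell_count * comp.group_a.mean
                 + comp.group_b.cell_count * comp.group_b.mean)
        assert total == pytest.approx(
            float(matrix.values[3].astype(np.float64).sum()), rel=1e-9)


class TestClusterMeans:
    def test_single_cluster_row_equals_global_means(self, tmp_path):
        m = cb.ExpressionMatrix(["gA", "gB"], ["c1", "c2"], [[1, 3], [0, 4]])
        store = build_store(m, tmp_path)
        f = cb.infer_field_kind("cl", ["only", "only"])
        hm = cluster_means(store, f, m.cell_ids, ["gA", "gB"])
        np.testing.assert_allclose(hm.matrix, [[2.0, 2.0]])

    def test_constant_gene_scales_to_zero(self, tmp_path):
        m = cb.ExpressionMatrix(["gA"], ["c1", "c2"], [[3, 3]])
        store = build_store(m, tmp_path)
        f = cb.infer_field_kind("cl", ["a", "a"])
        hm = cluster_means(store, f, m.cell_ids, ["gA"], scaling="per-gene")
        np.testing.assert_array_equal(hm.matrix, [[0.0]])

    def test_numeric_cluster_field_rejected(self, store, dataset, typed):
        age = next(f for f in typed if f.name == "age")
        with pytest.raises(QueryError, match="categorical"):
            cluster_means(store, age, dataset[1].cell_ids, ["GENE000"])

    def test_unknown_gene_skipped_with_warning(self, store, dataset, typed):
        from cellbundle._util import BuildLog
        cl = next(f for f in typed if f.name == "cluster")
        log = BuildLog()
        hm = cluster_means(store, cl, dataset[1].cell_ids,
                           ["GENE000", "NOPE"], log=log)
        assert hm.gene_ids == ["GENE000"] and log.warnings()

    def test_matches_dense_group_by_mean(self, dataset, store, typed):
        matrix, cells, *_ = dataset
        cl = next(f for f in typed if f.name == "cluster")
        genes = matrix.gene_ids[:16]
        hm = cluster_means(store, cl, cells.cell_ids, genes)
        labels = np.array(cells.columns["cluster"])
        for i, lab in enumerate(hm.cluster_labels):
            mask = labels == lab
            for j, g in enumerate(genes):
                want = matrix.values[matrix.gene_ids.index(g)][mask] \
                    .astype(np.float64).mean()
                assert hm.matrix[i, j] == pytest.approx(want, abs=1e-6)

    def test_permutation_invariance_in_cell_order(self, dataset, tmp_path):
        matrix, cells, *_ = dataset
        rng = np.random.default_rng(4)
        perm = rng.permutation(matrix.n_cells)
        pm = cb.ExpressionMatrix(matrix.gene_ids,
                                 [matrix.cell_ids[i] for i in perm],
                                 matrix.values[:, perm])
        pstore = build_store(pm, tmp_path)
        pf = cb.infer_field_kind("cluster",
                                 [cells.columns["cluster"][i] for i in perm])
        f = cb.infer_field_kind("cluster", cells.columns["cluster"])
        store2 = build_store(matrix, tmp_path / "orig")
        genes = matrix.gene_ids[:8]
        a = cluster_means(store2, f, matrix.cell_ids, genes)
        b = cluster_means(pstore, pf, pm.cell_ids, genes)
        assert a.cluster_labels == b.cluster_labels
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-6)
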