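"""Config parsing, bundle building/validation, collections, CLI surface."""

import numpy as np
import pytest
from click.testing import CliRunner

import cellbundle as cb
from cellbundle._util import BuildLog, load_json
from cellbundle.bundle import (CollectionNode, build_collection,
                               build_dataset, load_collection, open_bundle,
                               parse_config, validate_bundle)
from cellbundle.cli import main as cli_main
from cellbundle.io_import import BuildError
from cellbundle.matrix_store import DATA_FILE, fetch_gene


class TestConfig:
    def test_minimal_config_fills_defaults(self, tmp_path):
        p = tmp_path / "c.conf"
        p.write_text('name="d1"\nmatrix="m.tsv"\nmeta="meta.tsv"\n'
                     'coords=["t.tsv:tSNE"]\n')
        cfg = parse_config(p)
        assert cfg.n_bins == 10
        assert cfg.palette_expression == "reds"
        assert cfg.coords == [("t.tsv", "tSNE")]

    def test_missing_required_key_named(self, tmp_path):
        p = tmp_path / "c.conf"
        p.write_text('name="d1"\nmatrix="m.tsv"\ncoords=["t.tsv:t"]\n')
        with pytest.raises(BuildError, match="meta"):
            parse_config(p)

    def test_unknown_key_warns_not_fatal(self, tmp_path):
        p = tmp_path / "c.conf"
        p.write_text('name="d1"\nmatrix="m"\nmeta="m2"\ncoords=["t:t"]\n'
                     'bogusKey=1\n')
        log = BuildLog()
        parse_config(p, log)
        assert any("bogusKey" in w for w in log.warnings())

    def test_bad_dataset_name_rejected(self, tmp_path):
        p = tmp_path / "c.conf"
        p.write_text('name="bad name!"\nmatrix="m"\nmeta="m2"\n'
                     'coords=["t:t"]\n')
        with pytest.raises(BuildError, match="name"):
            parse_config(p)

    def test_generator_emitted_config_parses(self, synthetic_dir):
        cfg = parse_config(synthetic_dir / "cellbundle.conf")
        assert cfg.name == "synthetic"
        assert cfg.cluster_field == "cluster"
        assert [label for _, label in cfg.coords] == ["tSNE", "UMAP"]


class TestBuild:
    def test_smoke_minimal_dataset(self, tmp_path):
        spec = cb.SyntheticSpec(n_cells=20, n_genes=10, n_clusters=2,
                                markers_per_cluster=1, seed=5)
        cb.generate(spec, tmp_path / "in")
        cfg = parse_config(tmp_path / "in" / "cellbundle.conf")
        build_dataset(cfg, tmp_path / "out")
        report = validate_bundle(tmp_path / "out")
        assert report.passed, report.findings

    def test_missing_cluster_field_names_it(self, tmp_path, synthetic_dir):
        cfg = parse_config(synthetic_dir / "cellbundle.conf")
        cfg.cluster_field = "nonexistent"
        with pytest.raises(BuildError, match="nonexistent"):
            build_dataset(cfg, tmp_path / "out")

    def test_build_is_deterministic(self, tmp_path, synthetic_dir):
        cfg = parse_config(synthetic_dir / "cellbundle.conf")
        build_dataset(cfg, tmp_path / "a")
        build_dataset(cfg, tmp_path / "b")
        for rel in ["dataset.json", DATA_FILE, "exprMatrix.json",
                    "meta.tsv.gz", "heatmap.tsv", "coords/tSNE.tsv.gz",
                    "coords/UMAP.tsv.gz"]:
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes(), rel

    def test_queries_from_bundle_equal_dense_oracle(self, bundle, dataset):
        """Static sufficiency: answers from the bundle alone match the
        in-memory matrix."""
        matrix, cells, *_ = dataset
        rng = np.random.default_rng(8)
        for i in rng.integers(0, matrix.n_genes, size=10):
            np.testing.assert_array_equal(
                fetch_gene(bundle.store, matrix.gene_ids[i]),
                matrix.values[i])
        # selection via bundle metadata equals raw-table scan
        label = cells.columns["cluster"][0]
        sel = cb.select_cells(bundle.fields, bundle.cell_ids,
                              cb.SelectionQuery([cb.Predicate(
                                  "cluster", "equals", label)]))
        want = {c for c, v in zip(cells.cell_ids, cells.columns["cluster"])
                if v == label}
        assert sel == want

    def test_manifest_carries_legends_and_dicts(self, built_bundle):
        manifest = load_json(built_bundle / "dataset.json")
        fields = {f["name"]: f for f in manifest["fields"]}
        assert fields["cluster"]["kind"] == "categorical"
        total = sum(v["count"] for v in fields["cluster"]["values"])
        assert total == manifest["n_cells"]
        assert sum(fields["age"]["legend"]["bin_counts"]) \
            == manifest["n_cells"]


class TestValidate:
    def test_fresh_bundle_passes(self, built_bundle):
        assert validate_bundle(built_bundle).passed

    def test_truncated_data_file_detected(self, tmp_path, synthetic_dir):
        cfg = parse_config(synthetic_dir / "cellbundle.conf")
        build_dataset(cfg, tmp_path / "out")
        data = (tmp_path / "out" / DATA_FILE).read_bytes()
        (tmp_path / "out" / DATA_FILE).write_bytes(data[:-1])
        report = validate_bundle(tmp_path / "out")
        assert not report.passed
        assert any("store" in f for f in report.findings)

    def test_random_byte_flips_detected_or_harmless(self, tmp_path,
                                                    synthetic_dir):
        """Fuzz: every mutated bundle either still decodes every sampled
        gene identically or is flagged by validation."""
        cfg = parse_config(synthetic_dir / "cellbundle.conf")
        build_dataset(cfg, tmp_path / "ref")
        ref = open_bundle(tmp_path / "ref")
        ref_rows = {g: fetch_gene(ref.store, g)
                    for g in list(ref.store.index)[::20]}
        data = bytearray((tmp_path / "ref" / DATA_FILE).read_bytes())
        rng = np.random.default_rng(99)
        out = tmp_path / "mut"
        build_dataset(cfg, out)
        for _ in range(30):
            pos = int(rng.integers(0, len(data)))
            mutated = bytearray(data)
            mutated[pos] ^= 0xFF
            (out / DATA_FILE).write_bytes(bytes(mutated))
            report = validate_bundle(out)
            if report.passed:
                b = open_bundle(out)
                for g, row in ref_rows.items():
                    np.testing.assert_array_equal(fetch_gene(b.store, g), row)
        (out / DATA_FILE).write_bytes(bytes(data))


class TestCollection:
    def _tree(self):
        return CollectionNode("root", "Root", children=[
            CollectionNode("p1", "Project 1", children=[
                CollectionNode("d1", "DS 1", dataset="BUNDLE"),
                CollectionNode("d2", "DS 2", dataset="BUNDLE"),
            ]),
            CollectionNode("p2", "Project 2", children=[
                CollectionNode("d3", "DS 3", dataset="BUNDLE"),
                CollectionNode("d4", "DS 4", dataset="BUNDLE"),
            ]),
        ])

    def _fill(self, node, bundle_dir):
        if node.dataset == "BUNDLE":
            node.dataset = str(bundle_dir)
        for c in node.children:
            self._fill(c, bundle_dir)
        return node

    def test_single_dataset_root(self, tmp_path, built_bundle):
        root = CollectionNode("root", "Root", children=[
            CollectionNode("d1", "DS", dataset=str(built_bundle))])
        written = build_collection(root, tmp_path / "coll")
        assert len(written) == 1
        got = load_collection(tmp_path / "coll")
        assert got.children[0].dataset == str(built_bundle)

    def test_two_level_tree_counts(self, tmp_path, built_bundle):
        root = self._fill(self._tree(), built_bundle)
        written = build_collection(root, tmp_path / "coll")
        assert len(written) == 3  # root + 2 projects
        got = load_collection(tmp_path / "coll")
        leaves = [c for p in got.children for c in p.children]
        assert len(leaves) == 4 and all(l.is_leaf for l in leaves)

    def test_duplicate_sibling_names_rejected(self, tmp_path, built_bundle):
        root = CollectionNode("root", children=[
            CollectionNode("x", dataset=str(built_bundle)),
            CollectionNode("x", dataset=str(built_bundle))])
        with pytest.raises(BuildError, match="duplicate"):
            build_collection(root, tmp_path / "coll")

    def test_dangling_leaf_rejected(self, tmp_path):
        root = CollectionNode("root", children=[
            CollectionNode("x", dataset=str(tmp_path / "missing"))])
        with pytest.raises(BuildError, match="no built bundle"):
            build_collection(root, tmp_path / "coll")

    def test_random_tree_round_trip_isomorphic(self, tmp_path, built_bundle):
        """A seeded random 25-node hierarchy survives write+read unchanged."""
        rng = np.random.default_rng(55)
        counter = [0]

        def make(depth):
            counter[0] += 1
            name = f"n{counter[0]:02d}"
            if depth >= 3 or (depth > 0 and rng.random() < 0.4):
                return CollectionNode(name, name.upper(),
                                      dataset=str(built_bundle))
            n_children = int(rng.integers(2, 4))
            return CollectionNode(name, name.upper(),
                                  children=[make(depth + 1)
                                            for _ in range(n_children)])

        root = make(0)
        while counter[0] < 25:  # grow until 25 nodes
            root.children.append(make(1))
        build_collection(root, tmp_path / "coll")
        got = load_collection(tmp_path / "coll")

        def shape(n):
            return (n.name, n.short_label, n.dataset,
                    [shape(c) for c in n.children])

        assert shape(got) == shape(root)


class TestCli:
    def test_build_validate_and_query_roundtrip(self, tmp_path,
                                                synthetic_dir):
        runner = CliRunner()
        out = tmp_path / "bundle"
        r = runner.invoke(cli_main, ["build", "-c",
                                     str(synthetic_dir / "cellbundle.conf"),
                                     "-o", str(out)])
        assert r.exit_code == 0, r.output
        assert runner.invoke(cli_main, ["validate", str(out)]).exit_code == 0

        r = runner.invoke(cli_main, ["query", "gene", str(out), "GENE000"])
        assert r.exit_code == 0
        assert len(r.output.strip().splitlines()) == 1000

        r = runner.invoke(cli_main, ["query", "cells", str(out),
                                     "-f", "cluster=cluster1"])
        assert r.exit_code == 0 and r.output.strip()

        r = runner.invoke(cli_main, ["query", "violin", str(out), "GENE001",
                                     "-f", "cluster=cluster1"])
        assert r.exit_code == 0 and "selection" in r.output

        r = runner.invoke(cli_main, ["query", "heatmap", str(out)])
        assert r.exit_code == 0
        assert r.output.startswith("cluster\t")

    def test_query_peaks(self, built_bundle, synthetic_dir):
        runner = CliRunner()
        genes = (synthetic_dir / "genes.tsv").read_text().splitlines()[1:]
        symbol = genes[0].split("\t")[0]
        r = runner.invoke(cli_main, ["query", "peaks", str(built_bundle),
                                     symbol])
        assert r.exit_code == 0, r.output
        assert r.output.startswith("peak_id\t")

    def test_validate_fails_on_corruption(self, tmp_path, synthetic_dir):
        runner = CliRunner()
        out = tmp_path / "bundle"
        runner.invoke(cli_main, ["build", "-c",
                                 str(synthetic_dir / "cellbundle.conf"),
                                 "-o", str(out)])
        data = (out / DATA_FILE).read_bytes()
        (out / DATA_FILE).write_bytes(data[:-2])
        assert runner.invoke(cli_main,
                             ["validate", str(out)]).exit_code == 1
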