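"""Config parsing, static bundle assembly, collections, and validation.

A *bundle* is a self-contained directory from which every viewer operation
can be answered with plain file reads — no compute server:

    dataset.json      manifest: labels, typed fields + legends + colors,
                      layout list, dataset genes, digests, format version
    exprMatrix.bin    per-gene compressed expression blocks
    exprMatrix.json   store index (offsets, lengths, checksums, encoding)
    coords/<label>.tsv.gz   one file per layout
    meta.tsv.gz       the raw metadata table
    heatmap.tsv       cluster x dataset-genes mean table (when genes given)
    atac/             peaks.bed + genes.tsv when ATAC mode is configured

Builds are fully deterministic: no timestamps anywhere, gzip mtime pinned,
fixed JSON formatting — identical inputs give byte-identical bundles.

Many bundles can be arranged in a *collection*: a tree of named nodes whose
internal nodes each get an ``index.json`` listing their children, so a
static file server can serve the whole hierarchy from the root index alone.
"""

from __future__ import annotations

import ast
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate
from ._util import (BuildLog, dump_json, load_json, sha256_file,
                    sha256_text_list, write_gzip_text)
from .io_import import (BuildError, align_cells, read_annotations,
                        read_gene_list, read_layout, read_matrix_dense,
                        read_matrix_h5ad, read_matrix_loom, read_matrix_mtx)
from .matrix_store import (DATA_FILE, INDEX_FILE, MatrixStore, build_store,
                           fetch_gene, open_store)
from .model import Dataset
from .query import cluster_means

BUNDLE_FORMAT_VERSION = 1
MANIFEST_FILE = "dataset.json"

_REQUIRED_KEYS = ("name", "matrix", "meta", "coords")
_KNOWN_KEYS = {
    "name", "shortLabel", "matrix", "matrixFormat", "genesIn", "meta",
    "coords", "clusterField", "quickGenes", "atacPeaks", "atacGeneModels",
    "atacWindow", "paletteCategorical", "paletteExpression", "nBins",
    "stripSuffix", "images",
}


@dataclass
class DatasetConfig:
    """Parsed per-dataset build configuration (key=value dialect)."""

    name: str
    matrix: str
    meta: str
    coords: list[tuple[str, str]]          # (path, label)
    short_label: str = ""
    matrix_format: str = "auto"            # auto | mtx | dense | h5ad | loom
    genes_in: str = "rows"
    cluster_field: str | None = None
    quick_genes: str | None = None
    atac: dict | None = None               # {peaks, gene_models, window}
    palette_categorical: str = annotate.DEFAULT_QUALITATIVE
    palette_expression: str = annotate.DEFAULT_SEQUENTIAL
    n_bins: int = annotate.DEFAULT_N_BINS
    strip_suffix: bool = False
    images: list = field(default_factory=list)  # opaque passthrough
    base_dir: Path = Path(".")

    def path(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q


def parse_config(path, log: BuildLog | None = None) -> DatasetConfig:
    """Parse a flat key=value config (quoted strings, bracketed lists).

    Unknown keys warn but do not fail; missing required keys (name, matrix,
    meta, at least one coords entry) are errors naming the key.
    """
    path = Path(path)
    raw: dict[str, object] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                  start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise BuildError(f"{path}: line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key = key.strip()
        try:
            raw[key] = ast.literal_eval(value.strip())
        except (ValueError, SyntaxError):
            raise BuildError(f"{path}: line {lineno}: cannot parse value for "
                             f"{key!r}: {value.strip()!r}") from None
        if key not in _KNOWN_KEYS and log is not None:
            log.warn(f"{path}: unknown config key {key!r} ignored")

    for key in _REQUIRED_KEYS:
        if key not in raw or (key == "coords" and not raw[key]):
            raise BuildError(f"{path}: missing required config key {key!r}")

    name = str(raw["name"])
    if not all(c.isalnum() or c in "_-" for c in name) or not name:
        raise BuildError(f"{path}: dataset name {name!r} must match "
                         f"[A-Za-z0-9_-]+")

    coords: list[tuple[str, str]] = []
    for entry in raw["coords"]:
        if ":" in str(entry):
            p, _, label = str(entry).rpartition(":")
        else:
            p, label = str(entry), Path(str(entry)).stem
        coords.append((p, label))

    atac = None
    if "atacPeaks" in raw:
        if "atacGeneModels" not in raw:
            raise BuildError(f"{path}: atacPeaks requires atacGeneModels")
        atac = {"peaks": str(raw["atacPeaks"]),
                "gene_models": str(raw["atacGeneModels"]),
                "window": int(raw.get("atacWindow", 100_000))}

    return DatasetConfig(
        name=name,
        short_label=str(raw.get("shortLabel", name)),
        matrix=str(raw["matrix"]),
        matrix_format=str(raw.get("matrixFormat", "auto")),
        genes_in=str(raw.get("genesIn", "rows")),
        meta=str(raw["meta"]),
        coords=coords,
        cluster_field=(str(raw["clusterField"])
                       if "clusterField" in raw else None),
        quick_genes=str(raw["quickGenes"]) if "quickGenes" in raw else None,
        atac=atac,
        palette_categorical=str(raw.get("paletteCategorical",
                                        annotate.DEFAULT_QUALITATIVE)),
        palette_expression=str(raw.get("paletteExpression",
                                       annotate.DEFAULT_SEQUENTIAL)),
        n_bins=int(raw.get("nBins", annotate.DEFAULT_N_BINS)),
        strip_suffix=bool(raw.get("stripSuffix", False)),
        images=list(raw.get("images", [])),
        base_dir=path.parent,
    )


def _detect_format(config: DatasetConfig) -> str:
    if config.matrix_format != "auto":
        return config.matrix_format
    p = config.path(config.matrix)
    if p.is_dir():
        return "mtx"
    suffixes = "".join(p.suffixes)
    if ".h5ad" in suffixes:
        return "h5ad"
    if ".loom" in suffixes:
        return "loom"
    if ".mtx" in suffixes:
        return "mtx"
    return "dense"


def _import_dataset(config: DatasetConfig, log: BuildLog) -> Dataset:
    fmt = _detect_format(config)
    cells = layouts = None
    if fmt == "mtx":
        p = config.path(config.matrix)
        base = p if p.is_dir() else p.parent
        def _pick(stem: str) -> Path:
            for cand in (base / f"{stem}.tsv", base / f"{stem}.tsv.gz",
                         base / ("genes.tsv" if stem == "features" else "")):
                if cand.name and cand.exists():
                    return cand
            raise BuildError(f"{base}: cannot find {stem}.tsv[.gz]")
        mtx = p if p.is_file() else base / "matrix.mtx"
        if not mtx.exists() and (base / "matrix.mtx.gz").exists():
            mtx = base / "matrix.mtx.gz"
        matrix = read_matrix_mtx(mtx, _pick("features"), _pick("barcodes"), log)
    elif fmt == "dense":
        matrix = read_matrix_dense(config.path(config.matrix),
                                   genes_in=config.genes_in, log=log)
    elif fmt == "h5ad":
        matrix, cells, layouts = read_matrix_h5ad(config.path(config.matrix), log)
    elif fmt == "loom":
        matrix, cells, layouts = read_matrix_loom(config.path(config.matrix), log)
    else:
        raise BuildError(f"unknown matrix format {fmt!r}")

    # explicit meta/coords files override anything embedded in the container
    if cells is None or config.meta:
        cells = read_annotations(config.path(config.meta), log)
    if layouts is None or config.coords:
        layouts = [read_layout(config.path(p), label, log)
                   for p, label in config.coords]
    if not layouts:
        raise BuildError("no layouts: the build needs at least one 2D "
                         "coordinate set")
    return align_cells(matrix, cells, layouts,
                       strip_suffix=config.strip_suffix, log=log)


def _resolve_genes(genes: list[str], store_like, log: BuildLog) -> list[str]:
    out = []
    for g in genes:
        if g in store_like.gene_ids:
            out.append(g)
        elif g in store_like.aliases:
            out.append(store_like.aliases[g])
        else:
            log.warn(f"dataset gene {g!r} not found in matrix; skipped")
    return out


@dataclass
class DatasetBundle:
    directory: Path
    manifest: dict

    @property
    def name(self) -> str:
        return self.manifest["name"]


def build_dataset(config: DatasetConfig, out_dir,
                  log: BuildLog | None = None) -> DatasetBundle:
    """Run the full pipeline: import -> align -> store -> annotate ->
    heatmap -> manifest. Deterministic; any stage failure aborts with the
    stage name and cause."""
    log = log if log is not None else BuildLog()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "import"
    try:
        dataset = _import_dataset(config, log)
        if config.quick_genes:
            dataset.dataset_genes = _resolve_genes(
                read_gene_list(config.path(config.quick_genes)),
                dataset.matrix, log)

        stage = "annotate"
        fields = annotate.type_table(dataset.cells)
        if config.cluster_field is not None:
            by_name = {f.name: f for f in fields}
            if config.cluster_field not in by_name:
                raise BuildError(f"clusterField {config.cluster_field!r} not "
                                 f"in metadata; fields: "
                                 f"{', '.join(by_name)}")
            if by_name[config.cluster_field].kind != annotate.CATEGORICAL:
                raise BuildError(f"clusterField {config.cluster_field!r} is "
                                 f"{by_name[config.cluster_field].kind}, "
                                 f"needs categorical")
        for f in fields:
            if f.kind == annotate.CATEGORICAL:
                annotate.assign_colors(f, config.palette_categorical)
            elif f.kind == annotate.NUMERIC:
                finite = np.nan_to_num(f.numeric, nan=0.0)
                f.legend, f.bins = annotate.discretize_expression(
                    finite, n_bins=config.n_bins,
                    palette=config.palette_expression, log=log)

        stage = "store"
        store = build_store(dataset.matrix, out_dir)

        stage = "layouts"
        (out_dir / "coords").mkdir(exist_ok=True)
        layout_entries = []
        for layout in dataset.layouts:
            text = "cell\tx\ty\n" + "".join(
                f"{c}\t{x:.6f}\t{y:.6f}\n"
                for c, (x, y) in zip(layout.cell_ids, layout.coords))
            fname = f"coords/{layout.name}.tsv.gz"
            write_gzip_text(out_dir / fname, text)
            layout_entries.append({"name": layout.name, "file": fname,
                                   "sha256": sha256_file(out_dir / fname)})

        stage = "metadata"
        meta_text = "\t".join(dataset.cells.field_names) + "\n" + "".join(
            "\t".join(dataset.cells.columns[n][i]
                      for n in dataset.cells.field_names) + "\n"
            for i in range(dataset.n_cells))
        write_gzip_text(out_dir / "meta.tsv.gz", meta_text)

        stage = "heatmap"
        heatmap_entry = None
        if dataset.dataset_genes and config.cluster_field:
            cf = {f.name: f for f in fields}[config.cluster_field]
            hm = cluster_means(store, cf, dataset.cell_ids,
                               dataset.dataset_genes, scaling="per-gene",
                               log=log)
            (out_dir / "heatmap.tsv").write_text(hm.to_tsv(), encoding="utf-8",
                                                 newline="\n")
            heatmap_entry = {"file": "heatmap.tsv",
                             "clusters": hm.cluster_labels,
                             "genes": hm.gene_ids, "summary": hm.summary,
                             "scaling": hm.scaling}

        stage = "atac"
        atac_entry = None
        if config.atac is not None:
            (out_dir / "atac").mkdir(exist_ok=True)
            shutil.copyfile(config.path(config.atac["peaks"]),
                            out_dir / "atac" / "peaks.bed")
            shutil.copyfile(config.path(config.atac["gene_models"]),
                            out_dir / "atac" / "genes.tsv")
            atac_entry = {"peaks": "atac/peaks.bed",
                          "gene_models": "atac/genes.tsv",
                          "window": config.atac["window"]}

        stage = "manifest"
        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "name": config.name,
            "short_label": config.short_label,
            "n_cells": dataset.n_cells,
            "n_genes": dataset.matrix.n_genes,
            "cell_order_digest": sha256_text_list(dataset.cell_ids),
            "cluster_field": config.cluster_field,
            "dataset_genes": dataset.dataset_genes,
            "aliases": dataset.matrix.aliases,
            "defaults": {
                "n_bins": config.n_bins,
                "palette_categorical": config.palette_categorical,
                "palette_expression": config.palette_expression,
                "quartiles": "linear-interpolation",
            },
            "fields": [_field_to_manifest(f) for f in fields],
            "layouts": layout_entries,
            "meta": {"file": "meta.tsv.gz",
                     "sha256": sha256_file(out_dir / "meta.tsv.gz")},
            "matrix": {"data": DATA_FILE, "index": INDEX_FILE,
                       "sha256_data": sha256_file(out_dir / DATA_FILE)},
            "heatmap": heatmap_entry,
            "atac": atac_entry,
            "images": config.images,
            "build_log": {"warnings": log.warnings(), "counts": log.counts},
        }
        dump_json(manifest, out_dir / MANIFEST_FILE)
    except (BuildError, ValueError, OSError) as exc:
        raise BuildError(f"build failed at stage {stage!r}: {exc}") from exc
    return DatasetBundle(out_dir, manifest)


def _field_to_manifest(f: annotate.MetaField) -> dict:
    entry: dict = {"name": f.name, "kind": f.kind}
    if f.kind == annotate.CATEGORICAL:
        entry["values"] = [
            {"value": v, "code": code, "count": f.counts[v],
             "color": (f.color_map or {}).get(v)}
            for v, code in f.value_dict.items()
        ]
    elif f.kind == annotate.NUMERIC and f.legend is not None:
        entry["legend"] = {
            "breaks": f.legend.breaks, "n_bins": f.legend.n_bins,
            "bin_colors": f.legend.bin_colors,
            "bin_counts": f.legend.bin_counts, "zero_bin": f.legend.zero_bin,
        }
    return entry


# ---------------------------------------------------------------------------
# opening a bundle (static sufficiency: everything below reads only the
# bundle directory)


@dataclass
class OpenBundle:
    """Read-side handle onto a built bundle."""

    directory: Path
    manifest: dict
    store: MatrixStore
    cell_ids: list[str]
    fields: list[annotate.MetaField]

    def field(self, name: str) -> annotate.MetaField:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(f"no metadata field {name!r}; available: "
                       f"{', '.join(f.name for f in self.fields)}")

    def layout(self, name: str | None = None):
        entries = self.manifest["layouts"]
        entry = entries[0] if name is None else next(
            (e for e in entries if e["name"] == name), None)
        if entry is None:
            raise KeyError(f"no layout {name!r}; available: "
                           f"{', '.join(e['name'] for e in entries)}")
        from .io_import import read_layout
        return read_layout(self.directory / entry["file"], entry["name"])


def open_bundle(directory) -> OpenBundle:
    directory = Path(directory)
    manifest = load_json(directory / MANIFEST_FILE)
    store = open_store(directory, aliases=manifest.get("aliases") or {})
    if store.encoding["cell_order_digest"] != manifest["cell_order_digest"]:
        raise BuildError(f"{directory}: store cell order does not match the "
                         f"manifest (matrix/metadata drift)")
    cells = read_annotations(directory / manifest["meta"]["file"])
    fields = annotate.type_table(cells)
    pal = manifest["defaults"]
    for f in fields:
        if f.kind == annotate.CATEGORICAL:
            annotate.assign_colors(f, pal["palette_categorical"])
        elif f.kind == annotate.NUMERIC:
            finite = np.nan_to_num(f.numeric, nan=0.0)
            f.legend, f.bins = annotate.discretize_expression(
                finite, n_bins=pal["n_bins"],
                palette=pal["palette_expression"])
    return OpenBundle(directory, manifest, store, cells.cell_ids, fields)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    passed: bool
    findings: list[str]


def validate_bundle(directory) -> ValidationReport:
    """Integrity checks on a bundle directory. Failures are findings, not
    exceptions, so a report can list everything wrong at once."""
    directory = Path(directory)
    findings: list[str] = []

    try:
        manifest = load_json(directory / MANIFEST_FILE)
    except Exception as exc:  # noqa: BLE001 - any parse failure is a finding
        return ValidationReport(False, [f"manifest unreadable: {exc}"])

    n_cells = manifest.get("n_cells")
    try:
        store = open_store(directory, aliases=manifest.get("aliases") or {})
    except Exception as exc:  # noqa: BLE001
        return ValidationReport(False, [f"store index unreadable: {exc}"])

    if store.encoding.get("cell_order_digest") != manifest.get("cell_order_digest"):
        findings.append("store: cell order digest differs from manifest")
    if store.n_cells != n_cells:
        findings.append(f"store: n_cells {store.n_cells} != manifest {n_cells}")

    entries = sorted(store.index.values())
    expected_size = sum(length for _, length, _ in store.index.values())
    actual_size = (directory / DATA_FILE).stat().st_size \
        if (directory / DATA_FILE).exists() else -1
    if actual_size != expected_size:
        findings.append(f"store: data file is {actual_size} bytes, index "
                        f"expects {expected_size}")
    prev_end = 0
    for offset, length, _ in entries:
        if offset != prev_end:
            findings.append(f"store: block at offset {offset} does not abut "
                            f"previous end {prev_end}")
            break
        prev_end = offset + length

    genes = list(store.index)
    step = max(1, len(genes) // 20)
    for g in genes[::step]:
        try:
            vec = fetch_gene(store, g)
            if vec.size != n_cells:
                findings.append(f"store: gene {g!r} decodes to {vec.size} "
                                f"values, expected {n_cells}")
        except Exception as exc:  # noqa: BLE001
            findings.append(f"store: gene {g!r} failed to decode: {exc}")
            break

    for f in manifest.get("fields", []):
        if f["kind"] == annotate.CATEGORICAL:
            total = sum(v["count"] for v in f["values"])
            if total != n_cells:
                findings.append(f"field {f['name']!r}: counts sum to {total}, "
                                f"expected {n_cells}")
        elif f["kind"] == annotate.NUMERIC and f.get("legend"):
            total = sum(f["legend"]["bin_counts"])
            if total != n_cells:
                findings.append(f"field {f['name']!r}: legend bin counts sum "
                                f"to {total}, expected {n_cells}")

    for entry in manifest.get("layouts", []):
        p = directory / entry["file"]
        if not p.exists():
            findings.append(f"layout {entry['name']!r}: file missing")
            continue
        if sha256_file(p) != entry["sha256"]:
            findings.append(f"layout {entry['name']!r}: checksum mismatch")
            continue
        from .io_import import read_layout
        lay = read_layout(p, entry["name"])
        if len(lay.cell_ids) != n_cells:
            findings.append(f"layout {entry['name']!r}: {len(lay.cell_ids)} "
                            f"cells, expected {n_cells}")
        elif sha256_text_list(lay.cell_ids) != manifest["cell_order_digest"]:
            findings.append(f"layout {entry['name']!r}: cell order differs "
                            f"from canonical order")

    meta_entry = manifest.get("meta", {})
    p = directory / meta_entry.get("file", "meta.tsv.gz")
    if not p.exists():
        findings.append("metadata file missing")
    elif sha256_file(p) != meta_entry.get("sha256"):
        findings.append("metadata: checksum mismatch")

    data_sha = manifest.get("matrix", {}).get("sha256_data")
    if data_sha and (directory / DATA_FILE).exists() \
            and sha256_file(directory / DATA_FILE) != data_sha:
        findings.append("store: data file checksum differs from manifest")

    return ValidationReport(not findings, findings)


# ---------------------------------------------------------------------------
# collections


@dataclass
class CollectionNode:
    """A node of the dataset hierarchy: either an internal node with
    children, or a leaf referencing a built bundle directory."""

    name: str
    short_label: str = ""
    children: list["CollectionNode"] = field(default_factory=list)
    dataset: str | None = None  # path to a built bundle (leaf)

    @property
    def is_leaf(self) -> bool:
        return self.dataset is not None

    @classmethod
    def from_dict(cls, d: dict) -> "CollectionNode":
        return cls(
            name=d["name"],
            short_label=d.get("short_label", d["name"]),
            children=[cls.from_dict(c) for c in d.get("children", [])],
            dataset=d.get("dataset"),
        )


def _check_tree(node: CollectionNode, seen: set[int]) -> None:
    if id(node) in seen:
        raise BuildError(f"collection node {node.name!r} appears twice "
                         f"(tree must be acyclic with single parents)")
    seen.add(id(node))
    names = [c.name for c in node.children]
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise BuildError(f"duplicate sibling names under {node.name!r}: "
                         f"{sorted(dup)}")
    for child in node.children:
        _check_tree(child, seen)


def build_collection(root: CollectionNode, out_dir) -> list[Path]:
    """Write one index.json per internal node under out_dir, mirroring the
    tree as nested directories. Leaf entries point at their bundle
    directories (relative paths when possible); dangling leaves are errors.
    Returns the index files written."""
    out_dir = Path(out_dir)
    _check_tree(root, set())
    written: list[Path] = []

    def _emit(node: CollectionNode, node_dir: Path) -> None:
        node_dir.mkdir(parents=True, exist_ok=True)
        children_entries = []
        for child in node.children:
            if child.is_leaf:
                bundle_dir = Path(child.dataset)
                if not (bundle_dir / MANIFEST_FILE).exists():
                    raise BuildError(f"leaf {child.name!r} references "
                                     f"{bundle_dir}, which has no built bundle")
                children_entries.append({
                    "name": child.name, "short_label": child.short_label,
                    "kind": "dataset", "path": str(bundle_dir),
                })
            else:
                children_entries.append({
                    "name": child.name, "short_label": child.short_label,
                    "kind": "collection", "path": child.name,
                })
                _emit(child, node_dir / child.name)
        dump_json({"name": node.name, "short_label": node.short_label,
                   "children": children_entries}, node_dir / "index.json")
        written.append(node_dir / "index.json")

    if root.is_leaf:
        raise BuildError("collection root must be an internal node")
    _emit(root, out_dir)
    return written


def load_collection(out_dir) -> CollectionNode:
    """Reconstruct the hierarchy from the root index alone."""
    out_dir = Path(out_dir)

    def _load(node_dir: Path) -> CollectionNode:
        doc = load_json(node_dir / "index.json")
        node = CollectionNode(doc["name"], doc["short_label"])
        for entry in doc["children"]:
            if entry["kind"] == "dataset":
                node.children.append(CollectionNode(
                    entry["name"], entry["short_label"],
                    dataset=entry["path"]))
            else:
                node.children.append(_load(node_dir / entry["path"]))
        return node

    return _load(out_dir)
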