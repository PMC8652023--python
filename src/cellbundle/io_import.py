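"""Readers for every supported input format, plus cell alignment.

Supported matrix sources: MatrixMarket triples (matrix.mtx + features +
barcodes, Cellranger style), dense TSV/CSV (genes in rows or columns),
AnnData h5ad, and Loom. Metadata and layout coordinates come from TSV/CSV.
All readers return the canonical containers from :mod:`cellbundle.model`;
``align_cells`` intersects the three cell id sets and reorders everything to
the matrix column order.

Conventions pinned here (they matter for reproducibility):

* duplicate gene ids are suffixed ``_2``, ``_3``, ... in input order — never
  silently summed — so every row stays individually retrievable;
* two-column features files use column 2 (symbol) as the display id and keep
  column 1 (accession) as an alias, matching what users type into a search;
* delimiter detection is deterministic: tab if the header contains a tab,
  else comma;
* negative expression values are rejected, not clamped;
* cell id matching is exact; ``strip_suffix=True`` removes one trailing
  ``-<digits>`` barcode suffix before matching, and nothing fuzzier.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from ._util import BuildLog, open_maybe_gzip
from .model import CellTable, Dataset, ExpressionMatrix, Layout

MISSING_MARKERS = ("", "NA", "NaN")


class BuildError(ValueError):
    """Raised when an input file cannot be turned into a valid dataset."""


# ---------------------------------------------------------------------------
# helpers


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def dedup_gene_ids(gene_ids: list[str], log: BuildLog | None = None) -> list[str]:
    """Make gene ids unique by suffixing repeats with _2, _3, ... in order."""
    seen: dict[str, int] = {}
    out: list[str] = []
    n_dup = 0
    for g in gene_ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}_{seen[g]}")
            n_dup += 1
        else:
            seen[g] = 1
            out.append(g)
    if n_dup and log is not None:
        log.warn(f"{n_dup} duplicate gene ids renamed with _2/_3/... suffixes")
        log.count("genes.deduplicated", n_dup)
    return out


def _check_non_negative(values: np.ndarray, source: str) -> None:
    if values.size and float(values.min()) < 0:
        raise BuildError(f"{source}: negative expression values are not allowed "
                         f"(min={float(values.min())})")
    if values.size and not np.isfinite(values).all():
        raise BuildError(f"{source}: non-finite expression values")


def _read_id_column(path: Path | str) -> list[list[str]]:
    """Read a (possibly gzipped) TSV into split rows."""
    with open_maybe_gzip(path, "rt") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# MatrixMarket


def read_matrix_mtx(matrix_path, features_path, barcodes_path,
                    log: BuildLog | None = None) -> ExpressionMatrix:
    """Read a Cellranger-style MTX triple (genes in rows, cells in columns).

    Features files with two or more columns use column 2 as the display gene
    id and keep column 1 as an alias; single-column files use column 1.
    """
    with open_maybe_gzip(matrix_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat) if scipy.sparse.issparse(mat) else np.asarray(mat)
    n_genes, n_cells = mat.shape

    feat_rows = _read_id_column(features_path)
    barcodes = [row[0] for row in _read_id_column(barcodes_path)]
    if len(feat_rows) != n_genes or len(barcodes) != n_cells:
        raise BuildError(
            f"MTX dimensions {n_genes} x {n_cells} do not match sidecar files: "
            f"features has {len(feat_rows)} lines, barcodes has {len(barcodes)} lines"
        )

    if feat_rows and len(feat_rows[0]) >= 2:
        raw_ids = [row[1] for row in feat_rows]
        accessions = [row[0] for row in feat_rows]
    else:
        raw_ids = [row[0] for row in feat_rows]
        accessions = None

    gene_ids = dedup_gene_ids(raw_ids, log)
    aliases = {}
    if accessions is not None:
        aliases = {acc: gid for acc, gid in zip(accessions, gene_ids) if acc != gid}

    dense = mat.toarray() if scipy.sparse.issparse(mat) else mat
    dense = np.asarray(dense, dtype=np.float32)
    _check_non_negative(dense, str(matrix_path))
    return ExpressionMatrix(gene_ids, barcodes, dense, aliases)


# ---------------------------------------------------------------------------
# dense TSV/CSV


def read_matrix_dense(path, genes_in: str = "rows",
                      log: BuildLog | None = None) -> ExpressionMatrix:
    """Read a dense matrix: one header row of ids plus one leading id column.

    ``genes_in`` says whether genes are the rows (default) or the columns.
    Parsing is by hand so errors can name the offending line and column.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    with open_maybe_gzip(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise BuildError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])
    header = lines[0].split(delim)
    col_ids = header[1:]
    n_cols = len(header)

    row_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(delim)
        if len(parts) != n_cols:
            raise BuildError(f"{path}: line {lineno} has {len(parts)} fields, "
                             f"expected {n_cols}")
        row_ids.append(parts[0])
        try:
            rows.append(np.array([float(x) for x in parts[1:]], dtype=np.float32))
        except ValueError:
            for col, x in enumerate(parts[1:], start=2):
                try:
                    float(x)
                except ValueError:
                    raise BuildError(f"{path}: non-numeric value {x!r} at line "
                                     f"{lineno}, column {col}") from None
            raise

    values = np.vstack(rows) if rows else np.zeros((0, len(col_ids)), dtype=np.float32)
    if genes_in == "columns":
        values = values.T.copy()
        row_ids, col_ids = col_ids, row_ids
    gene_ids = dedup_gene_ids(row_ids, log)
    _check_non_negative(values, str(path))
    return ExpressionMatrix(gene_ids, col_ids, values)


# ---------------------------------------------------------------------------
# AnnData h5ad


def read_matrix_h5ad(path, log: BuildLog | None = None
                     ) -> tuple[ExpressionMatrix, CellTable, list[Layout]]:
    """Read an AnnData container: X (transposed to gene x cell), obs columns
    as raw metadata fields, and every 2D obsm embedding as a Layout (leading
    "X_" stripped from the key)."""
    import anndata

    adata = anndata.read_h5ad(path)
    x = adata.X
    if scipy.sparse.issparse(x):
        x = x.toarray()
    values = np.asarray(x, dtype=np.float32).T  # cells x genes -> genes x cells
    cell_ids = [str(c) for c in adata.obs_names]
    gene_ids = dedup_gene_ids([str(g) for g in adata.var_names], log)
    aliases = {}
    if "accession" in adata.var.columns:
        aliases = {str(a): g for a, g in zip(adata.var["accession"], gene_ids)
                   if str(a) != g}
    _check_non_negative(values, str(path))
    matrix = ExpressionMatrix(gene_ids, cell_ids, values, aliases)

    field_names = ["cellId"] + [str(c) for c in adata.obs.columns]
    columns = {"cellId": list(cell_ids)}
    for col in adata.obs.columns:
        columns[str(col)] = [str(v) for v in adata.obs[col]]
    cells = CellTable(cell_ids, field_names, columns)

    layouts: list[Layout] = []
    for key in adata.obsm.keys():
        arr = np.asarray(adata.obsm[key])
        if arr.ndim != 2 or arr.shape[1] < 2:
            continue
        if arr.shape[1] > 2 and log is not None:
            log.info(f"embedding {key!r} has {arr.shape[1]} columns; using first two")
        name = key[2:] if key.startswith("X_") else key
        layouts.append(Layout(name, list(cell_ids), arr[:, :2].astype(np.float64)))
    if not layouts and log is not None:
        log.warn(f"{path}: no 2D embedding found; layout list is empty")
    return matrix, cells, layouts


# ---------------------------------------------------------------------------
# Loom


_LOOM_GENE_ATTRS = ("Gene", "var_names", "gene_ids", "GeneID", "Accession")
_LOOM_CELL_ATTRS = ("CellID", "obs_names", "cell_ids", "Cell")


def _loom_str(arr) -> list[str]:
    return [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in arr[:]]


def read_matrix_loom(path, log: BuildLog | None = None
                     ) -> tuple[ExpressionMatrix, CellTable, list[Layout]]:
    """Read a Loom file (HDF5 with /matrix as genes x cells, /row_attrs and
    /col_attrs). Column attribute pairs following the ``_X``/``_Y`` or
    ``_tSNE1``/``_tSNE2`` suffix convention become Layouts."""
    import h5py

    with h5py.File(path, "r") as f:
        row_attrs = f["row_attrs"] if "row_attrs" in f else {}
        col_attrs = f["col_attrs"] if "col_attrs" in f else {}
        gene_attr = next((a for a in _LOOM_GENE_ATTRS
                          if a in row_attrs and a != "Accession"), None)
        cell_attr = next((a for a in _LOOM_CELL_ATTRS if a in col_attrs), None)
        if gene_attr is None or cell_attr is None:
            raise BuildError(
                f"{path}: missing gene/cell id attributes; row_attrs="
                f"{sorted(row_attrs)}, col_attrs={sorted(col_attrs)}"
            )
        gene_ids = dedup_gene_ids(_loom_str(row_attrs[gene_attr]), log)
        cell_ids = _loom_str(col_attrs[cell_attr])
        values = np.asarray(f["matrix"][:], dtype=np.float32)
        aliases = {}
        if "Accession" in row_attrs:
            aliases = {a: g for a, g in zip(_loom_str(row_attrs["Accession"]), gene_ids)
                       if a != g}
        _check_non_negative(values, str(path))
        matrix = ExpressionMatrix(gene_ids, cell_ids, values, aliases)

        meta_names, columns = ["cellId"], {"cellId": list(cell_ids)}
        coord_attrs: set[str] = set()
        layouts: list[Layout] = []
        attr_names = sorted(col_attrs)
        # _X/_Y pair -> "layout"; _<base>1/_<base>2 pair -> "<base>"
        if "_X" in col_attrs and "_Y" in col_attrs:
            xy = np.column_stack([col_attrs["_X"][:], col_attrs["_Y"][:]])
            layouts.append(Layout("layout", list(cell_ids), xy.astype(np.float64)))
            coord_attrs.update(("_X", "_Y"))
        for name in attr_names:
            if name.startswith("_") and name.endswith("1"):
                partner = name[:-1] + "2"
                if partner in col_attrs:
                    xy = np.column_stack([col_attrs[name][:], col_attrs[partner][:]])
                    layouts.append(Layout(name[1:-1], list(cell_ids),
                                          xy.astype(np.float64)))
                    coord_attrs.update((name, partner))
        for name in attr_names:
            if name == cell_attr or name in coord_attrs or name.startswith("_"):
                continue
            meta_names.append(name)
            columns[name] = _loom_str(col_attrs[name])
        if not layouts and log is not None:
            log.warn(f"{path}: no paired coordinate attributes; layout list empty")
        cells = CellTable(cell_ids, meta_names, columns)
    return matrix, cells, layouts


# ---------------------------------------------------------------------------
# metadata and layouts


def read_annotations(path, log: BuildLog | None = None) -> CellTable:
    """Read the per-cell metadata table (first column = cell id, one header
    row). Field typing is deferred to :func:`cellbundle.annotate.type_table`."""
    with open_maybe_gzip(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise BuildError(f"{path}: empty metadata file")
    delim = _detect_delimiter(lines[0])
    header = lines[0].split(delim)
    cell_ids: list[str] = []
    columns: dict[str, list[str]] = {name: [] for name in header}
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(delim)
        if len(parts) != len(header):
            raise BuildError(f"{path}: line {lineno} has {len(parts)} fields, "
                             f"expected {len(header)}")
        if parts[0] in seen:
            raise BuildError(f"{path}: duplicate cell id {parts[0]!r} at line {lineno}")
        seen.add(parts[0])
        cell_ids.append(parts[0])
        for name, value in zip(header, parts):
            columns[name].append(value)
    return CellTable(cell_ids, header, columns)


def read_layout(path, name: str, log: BuildLog | None = None) -> Layout:
    """Read a cell/x/y coordinate table. Rows with non-finite coordinates are
    dropped and counted in the build log."""
    with open_maybe_gzip(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise BuildError(f"{path}: empty layout file")
    delim = _detect_delimiter(lines[0])
    if len(lines[0].split(delim)) < 3:
        raise BuildError(f"{path}: layout needs at least 3 columns (cell, x, y)")
    cell_ids: list[str] = []
    coords: list[tuple[float, float]] = []
    n_dropped = 0
    for line in lines[1:]:
        parts = line.split(delim)
        try:
            x, y = float(parts[1]), float(parts[2])
        except (ValueError, IndexError):
            x, y = float("nan"), float("nan")
        if not (np.isfinite(x) and np.isfinite(y)):
            n_dropped += 1
            continue
        cell_ids.append(parts[0])
        coords.append((x, y))
    if n_dropped and log is not None:
        log.warn(f"{path}: dropped {n_dropped} rows with non-finite coordinates")
        log.count(f"layout.{name}.dropped_nonfinite", n_dropped)
    arr = np.array(coords, dtype=np.float64) if coords else np.zeros((0, 2))
    return Layout(name, cell_ids, arr)


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line; blanks and # comments skipped."""
    with open_maybe_gzip(path, "rt") as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]


# ---------------------------------------------------------------------------
# alignment

_SUFFIX_RE = re.compile(r"-\d+$")


def _strip(ids: list[str]) -> list[str]:
    return [_SUFFIX_RE.sub("", c) for c in ids]


def align_cells(matrix: ExpressionMatrix, cells: CellTable, layouts: list[Layout],
                strip_suffix: bool = False, log: BuildLog | None = None) -> Dataset:
    """Intersect cell ids across matrix, metadata and layouts and reorder all
    three to the matrix column order (the canonical order).

    Cells missing from any source are dropped with per-source counts in the
    build log. An empty intersection is an error that reports per-source
    counts and example ids, since it almost always means an id convention
    mismatch rather than genuinely disjoint data.
    """
    log = log if log is not None else BuildLog()
    if strip_suffix:
        matrix = ExpressionMatrix(matrix.gene_ids, _strip(matrix.cell_ids),
                                  matrix.values, matrix.aliases)
        cells = CellTable(_strip(cells.cell_ids), cells.field_names,
                          {n: list(v) for n, v in cells.columns.items()}
                          | {cells.field_names[0]: _strip(cells.cell_ids)})
        layouts = [Layout(l.name, _strip(l.cell_ids), l.coords) for l in layouts]

    common = set(matrix.cell_ids) & set(cells.cell_ids)
    for layout in layouts:
        common &= set(layout.cell_ids)
    if not common:
        parts = [f"matrix: {matrix.n_cells} cells e.g. {matrix.cell_ids[:3]}",
                 f"metadata: {cells.n_cells} cells e.g. {cells.cell_ids[:3]}"]
        for layout in layouts:
            parts.append(f"layout {layout.name!r}: {len(layout.cell_ids)} cells "
                         f"e.g. {layout.cell_ids[:3]}")
        raise BuildError("no cells shared across matrix, metadata and layouts; "
                         + "; ".join(parts))

    order = [c for c in matrix.cell_ids if c in common]
    log.count("align.dropped_from_matrix", matrix.n_cells - len(order))
    log.count("align.dropped_from_meta", cells.n_cells - len(order))
    for layout in layouts:
        log.count(f"align.dropped_from_layout.{layout.name}",
                  len(layout.cell_ids) - len(order))
    for key, n in list(log.counts.items()):
        if key.startswith("align.") and n:
            log.info(f"{key}: {n} cells dropped")

    col = {c: i for i, c in enumerate(matrix.cell_ids)}
    idx = [col[c] for c in order]
    sub_matrix = ExpressionMatrix(matrix.gene_ids, order,
                                  matrix.values[:, idx], matrix.aliases)
    return Dataset(
        matrix=sub_matrix,
        cells=cells.subset(order),
        layouts=[layout.subset(order) for layout in layouts],
    )


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers; used by the synthetic
# generator and by conversion tooling)


def write_mtx(matrix: ExpressionMatrix, out_dir,
              accessions: list[str] | None = None) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv. If ``accessions`` is
    given, features.tsv is two-column (accession, symbol)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sparse)
    with open(out_dir / "features.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for i, g in enumerate(matrix.gene_ids):
            if accessions is not None:
                fh.write(f"{accessions[i]}\t{g}\n")
            else:
                fh.write(g + "\n")
    with open(out_dir / "barcodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(c + "\n" for c in matrix.cell_ids)


def write_dense(matrix: ExpressionMatrix, path) -> None:
    """Write a genes-in-rows dense TSV with a gene column and cell id header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(matrix.cell_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(format(float(v), "g") for v in row) + "\n")


def write_h5ad(matrix: ExpressionMatrix, cells: CellTable,
               layouts: list[Layout], path) -> None:
    import anndata
    import pandas as pd

    obs = pd.DataFrame(
        {n: cells.columns[n] for n in cells.field_names[1:]},
        index=pd.Index(cells.cell_ids, name="cellId"),
    )
    var = pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene"))
    if matrix.aliases:
        sym_to_acc = {g: a for a, g in matrix.aliases.items()}
        var["accession"] = [sym_to_acc.get(g, g) for g in matrix.gene_ids]
    adata = anndata.AnnData(X=matrix.values.T.copy(), obs=obs, var=var)
    for layout in layouts:
        adata.obsm[f"X_{layout.name}"] = layout.coords.copy()
    adata.write_h5ad(path)


def write_loom(matrix: ExpressionMatrix, cells: CellTable,
               layouts: list[Layout], path) -> None:
    import h5py

    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=matrix.values)
        ra = f.create_group("row_attrs")
        ra.create_dataset("Gene", data=matrix.gene_ids, dtype=str_dt)
        if matrix.aliases:
            sym_to_acc = {g: a for a, g in matrix.aliases.items()}
            ra.create_dataset("Accession",
                              data=[sym_to_acc.get(g, g) for g in matrix.gene_ids],
                              dtype=str_dt)
        ca = f.create_group("col_attrs")
        ca.create_dataset("CellID", data=cells.cell_ids, dtype=str_dt)
        for name in cells.field_names[1:]:
            ca.create_dataset(name, data=cells.columns[name], dtype=str_dt)
        for layout in layouts:
            ca.create_dataset(f"_{layout.name}1", data=layout.coords[:, 0])
            ca.create_dataset(f"_{layout.name}2", data=layout.coords[:, 1])
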