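"""Canonical in-memory containers shared by the importers and the builder.

The pipeline's unit of work is a ``Dataset``: a gene x cell expression matrix,
a per-cell metadata table, and one or more 2D embedding layouts, all indexed
by the same ordered list of cell identifiers (the *canonical order*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionMatrix:
    """Gene x cell numeric matrix with identifier axes.

    ``values`` is a dense float32 array of shape (n_genes, n_cells); values
    are non-negative and finite (counts or normalized expression, whatever the
    input supplied — nothing downstream re-normalizes). ``aliases`` maps
    secondary identifiers (e.g. Ensembl accessions from a two-column features
    file) onto the display gene id.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            seen: set[str] = set()
            dup = next(c for c in self.cell_ids if c in seen or seen.add(c))
            raise ValueError(f"duplicate cell id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class CellTable:
    """Per-cell metadata: an ordered cell id column plus raw string fields.

    Fields are kept as raw text until :func:`cellbundle.annotate.type_table`
    classifies each one as categorical, numeric, or uniqueId. The identifier
    column itself is field 0 with kind ``uniqueId``.
    """

    cell_ids: list[str]
    field_names: list[str]
    columns: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            seen: set[str] = set()
            dup = next(c for c in self.cell_ids if c in seen or seen.add(c))
            raise ValueError(f"duplicate cell id in metadata: {dup!r}")
        for name in self.field_names:
            if len(self.columns[name]) != len(self.cell_ids):
                raise ValueError(f"field {name!r} has wrong length")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, order: list[str]) -> "CellTable":
        """Reorder/restrict to the given cell ids (must all be present)."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in order]
        return CellTable(
            cell_ids=list(order),
            field_names=list(self.field_names),
            columns={n: [self.columns[n][i] for i in idx] for n in self.field_names},
        )


@dataclass
class Layout:
    """One named 2D embedding (tSNE, UMAP, ...): an (n_cells, 2) float array
    aligned to ``cell_ids``. Coordinates are in arbitrary embedding units."""

    name: str
    cell_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.cell_ids), 2):
            raise ValueError(
                f"layout {self.name!r}: coords shape {self.coords.shape} "
                f"does not match {len(self.cell_ids)} cells x 2"
            )
        if self.coords.size and not np.isfinite(self.coords).all():
            raise ValueError(f"layout {self.name!r} contains non-finite coordinates")

    def subset(self, order: list[str]) -> "Layout":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in order]
        return Layout(self.name, list(order), self.coords[idx])


@dataclass
class Dataset:
    """A matrix, metadata table and layouts over one canonical cell order."""

    matrix: ExpressionMatrix
    cells: CellTable
    layouts: list[Layout]
    dataset_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = self.matrix.cell_ids
        if self.cells.cell_ids != order:
            raise ValueError("metadata cell order differs from matrix order")
        for layout in self.layouts:
            if layout.cell_ids != order:
                raise ValueError(f"layout {layout.name!r} order differs from matrix")
        known = set(self.matrix.gene_ids)
        missing = [g for g in self.dataset_genes if g not in known]
        if missing:
            raise ValueError(f"dataset genes absent from matrix: {missing[:3]}")

    @property
    def cell_ids(self) -> list[str]:
        return self.matrix.cell_ids

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells
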