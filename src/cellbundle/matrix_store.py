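"""Per-gene random-access compressed expression store.

The whole point of a static bundle is that a viewer (or this library) can
fetch one gene's expression vector without touching the rest of the matrix.
The store is two files inside the bundle directory:

* ``exprMatrix.bin`` — concatenated per-gene blocks, each block the zlib
  (deflate) compression of the gene's float32 little-endian cell vector,
  written in gene order;
* ``exprMatrix.json`` — the sidecar index: for every gene its
  ``[byte_offset, byte_length, crc32]``, plus an encoding descriptor with the
  value type, compression, store format version, cell count and a digest of
  the canonical cell id order.

Keeping the index in a sidecar (rather than embedded in the data file) means
a plain HTTP range request can serve any single gene — no server-side code.
Compression level and value layout are fixed, so the same matrix always
produces byte-identical store files.

Gene aliases (accession → symbol) are *not* part of the store files; they
live in the bundle manifest and are attached to the in-memory handle by the
opener, so stores built from alias-free formats stay byte-identical to
stores built from alias-carrying ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import closest_ids, dump_json, load_json, sha256_text_list
from .model import ExpressionMatrix

STORE_FORMAT_VERSION = 1
_COMPRESSION_LEVEL = 6  # fixed: determinism is part of the format contract

DATA_FILE = "exprMatrix.bin"
INDEX_FILE = "exprMatrix.json"


class StoreError(RuntimeError):
    """Raised for corrupt stores or failed lookups."""


class GeneNotFoundError(KeyError):
    """Unknown gene id; carries the closest known ids as suggestions."""

    def __init__(self, gene_id: str, suggestions: list[str]):
        super().__init__(gene_id)
        self.gene_id = gene_id
        self.suggestions = suggestions

    def __str__(self) -> str:
        return (f"gene not found: {self.gene_id!r}; "
                f"closest ids: {', '.join(self.suggestions)}")


@dataclass
class MatrixStore:
    """Handle onto an on-disk store. Open with :func:`open_store`."""

    directory: Path
    index: dict[str, tuple[int, int, int]]  # gene -> (offset, length, crc32)
    n_cells: int
    encoding: dict
    aliases: dict[str, str] = field(default_factory=dict)

    @property
    def data_path(self) -> Path:
        return self.directory / DATA_FILE

    def resolve(self, gene_id: str) -> str:
        if gene_id in self.index:
            return gene_id
        if gene_id in self.aliases and self.aliases[gene_id] in self.index:
            return self.aliases[gene_id]
        raise GeneNotFoundError(
            gene_id, closest_ids(gene_id, list(self.index) + list(self.aliases)))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.index or gene_id in self.aliases


def build_store(matrix: ExpressionMatrix, out_dir) -> MatrixStore:
    """Write the store for a canonical matrix. Deterministic: identical input
    always produces byte-identical ``exprMatrix.bin``/``exprMatrix.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index: dict[str, tuple[int, int, int]] = {}
    offset = 0
    with open(out_dir / DATA_FILE, "wb") as fh:
        for i, gene in enumerate(matrix.gene_ids):
            vec = np.ascontiguousarray(matrix.values[i], dtype="<f4")
            if not np.isfinite(vec).all():
                raise ValueError(f"gene {gene!r} has non-finite values")
            block = zlib.compress(vec.tobytes(), _COMPRESSION_LEVEL)
            index[gene] = (offset, len(block), zlib.crc32(block))
            fh.write(block)
            offset += len(block)
    encoding = {
        "format_version": STORE_FORMAT_VERSION,
        "value_type": "float32",
        "compression": "deflate",
        "n_cells": matrix.n_cells,
        "cell_order_digest": sha256_text_list(matrix.cell_ids),
    }
    dump_json(
        {"encoding": encoding,
         "genes": {g: list(entry) for g, entry in index.items()}},
        out_dir / INDEX_FILE,
    )
    return MatrixStore(out_dir, index, matrix.n_cells, encoding,
                       dict(matrix.aliases))


def open_store(directory, aliases: dict[str, str] | None = None) -> MatrixStore:
    """Open a store knowing only its directory (the bundle is self-describing)."""
    directory = Path(directory)
    doc = load_json(directory / INDEX_FILE)
    enc = doc["encoding"]
    if enc.get("format_version") != STORE_FORMAT_VERSION:
        raise StoreError(f"unsupported store format version: "
                         f"{enc.get('format_version')!r}")
    index = {g: tuple(v) for g, v in doc["genes"].items()}
    return MatrixStore(directory, index, enc["n_cells"], enc, aliases or {})


def fetch_gene(store: MatrixStore, gene_id: str) -> np.ndarray:
    """Return one gene's per-cell vector (canonical cell order).

    I/O is bounded by the gene's block: a seek plus one read of
    ``byte_length`` bytes, never a scan of the matrix.
    """
    gene = store.resolve(gene_id)
    offset, length, crc = store.index[gene]
    with open(store.data_path, "rb") as fh:
        fh.seek(offset)
        block = fh.read(length)
    if len(block) != length or zlib.crc32(block) != crc:
        raise StoreError(f"store corruption: block for gene {gene!r} fails its "
                         f"checksum (read {len(block)} of {length} bytes)")
    vec = np.frombuffer(zlib.decompress(block), dtype="<f4")
    if vec.size != store.n_cells:
        raise StoreError(f"gene {gene!r} decodes to {vec.size} values, "
                         f"expected {store.n_cells}")
    return vec.astype(np.float32)


def list_genes(store: MatrixStore) -> list[str]:
    """Gene ids in stored (build) order."""
    return list(store.index)
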