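"""Headless equivalents of the interactive operations: metadata filtering
(Find Cells), cell id export (Export Cells), violin comparison of a gene in
a selection versus background, and the cluster x dataset-genes heatmap table.

All operations work from the per-gene store plus typed metadata fields, so
they can be answered from a built bundle alone — no original inputs needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import BuildLog
from .annotate import CATEGORICAL, NUMERIC, UNIQUE_ID, MetaField, _norm_missing
from .matrix_store import MatrixStore, fetch_gene

OPERATORS = ("equals", "in", "range", "gt", "lt")


class QueryError(ValueError):
    pass


@dataclass
class Predicate:
    field: str
    op: str  # equals | in | range | gt | lt
    operand: object  # str, set/list of str, (low, high), or number

    def __post_init__(self) -> None:
        if self.op not in OPERATORS:
            raise QueryError(f"unknown operator {self.op!r}; one of {OPERATORS}")
        if self.op == "range":
            low, high = self.operand  # type: ignore[misc]
            if float(low) > float(high):
                raise QueryError(f"range low {low} > high {high}")


@dataclass
class SelectionQuery:
    """A conjunction of predicates over metadata fields.

    Only AND-combination is supported, matching a filter panel where each
    added filter narrows the selection; an empty predicate list selects all
    cells (the vacuous conjunction).
    """

    predicates: list[Predicate] = field(default_factory=list)


def parse_predicate(text: str) -> Predicate:
    """Parse one CLI-style filter: ``field=value``, ``field=a,b`` (in-set),
    ``field=lo..hi`` (closed range), ``field>x``, ``field<x``."""
    for sym, op in ((">", "gt"), ("<", "lt")):
        if sym in text:
            name, _, val = text.partition(sym)
            return Predicate(name.strip(), op, float(val))
    if "=" not in text:
        raise QueryError(f"cannot parse filter {text!r}")
    name, _, val = text.partition("=")
    if ".." in val:
        low, _, high = val.partition("..")
        return Predicate(name.strip(), "range", (float(low), float(high)))
    if "," in val:
        return Predicate(name.strip(), "in", [v.strip() for v in val.split(",")])
    return Predicate(name.strip(), "equals", val.strip())


def _predicate_mask(f: MetaField, pred: Predicate) -> np.ndarray:
    n = f.n_cells
    if pred.op in ("equals", "in"):
        wanted = ({str(pred.operand)} if pred.op == "equals"
                  else {str(v) for v in pred.operand})
        if f.kind == NUMERIC:
            nums = set()
            for w in wanted:
                try:
                    nums.add(float(w))
                except ValueError:
                    pass
            return np.array([(not np.isnan(x)) and x in nums for x in f.numeric])
        values = ([_norm_missing(v) for v in f.values]
                  if f.kind == CATEGORICAL else f.values)
        return np.array([v in wanted for v in values])
    # numeric comparisons
    if f.kind != NUMERIC:
        raise QueryError(f"operator {pred.op!r} needs a numeric field but "
                         f"{f.name!r} is {f.kind}")
    x = f.numeric
    with np.errstate(invalid="ignore"):
        if pred.op == "range":
            low, high = pred.operand  # type: ignore[misc]
            return (x >= float(low)) & (x <= float(high))
        if pred.op == "gt":
            return x > float(pred.operand)
        return x < float(pred.operand)


def select_cells(fields: list[MetaField], cell_ids: list[str],
                 q: SelectionQuery) -> set[str]:
    """Cells satisfying ALL predicates. Categorical operands compare decoded
    values; numeric operands compare parsed numbers; range is closed."""
    by_name = {f.name: f for f in fields}
    mask = np.ones(len(cell_ids), dtype=bool)
    for pred in q.predicates:
        if pred.field not in by_name:
            raise QueryError(f"unknown field {pred.field!r}; fields: "
                             f"{', '.join(by_name)}")
        mask &= _predicate_mask(by_name[pred.field], pred)
    return {c for c, m in zip(cell_ids, mask) if m}


def export_cells(selection: set[str], cell_ids: list[str], out_path) -> int:
    """Write selected cell ids one per line in canonical order (LF endings);
    returns the line count."""
    ordered = [c for c in cell_ids if c in selection]
    Path(out_path).write_text("".join(c + "\n" for c in ordered),
                              encoding="utf-8", newline="\n")
    return len(ordered)


# ---------------------------------------------------------------------------
# violin


@dataclass
class GroupStats:
    cell_count: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    values: np.ndarray

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupStats":
        v = np.asarray(values, dtype=np.float64)
        # linear-interpolation quartiles: the most common convention, pinned
        # here (and in the manifest) for cross-language reproducibility
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        return cls(int(v.size), float(v.mean()), float(med), float(q1),
                   float(q3), float(v.min()), float(v.max()), v)


@dataclass
class ViolinComparison:
    gene_id: str
    group_a: GroupStats  # the selection
    group_b: GroupStats  # background, or all other cells
    background_overlap_removed: int = 0


def violin_stats(store: MatrixStore, gene_id: str, selection: set[str],
                 cell_ids: list[str], background: set[str] | None = None,
                 log: BuildLog | None = None) -> ViolinComparison:
    """Summary statistics of one gene in a selection versus a comparison
    group (an explicit background set, or all remaining cells).

    Background cells that are also selected are removed from the background
    with a logged count — mirroring a UI where "background" is a loose set —
    and an empty comparison group is an error.
    """
    if not selection:
        raise QueryError("selection is empty")
    vec = fetch_gene(store, gene_id)
    pos = {c: i for i, c in enumerate(cell_ids)}
    sel_idx = [pos[c] for c in cell_ids if c in selection]
    overlap = 0
    if background is None:
        other = [i for c, i in ((c, pos[c]) for c in cell_ids)
                 if c not in selection]
    else:
        overlap = len(background & selection)
        if overlap and log is not None:
            log.warn(f"removed {overlap} cells from background that are also "
                     f"in the selection")
        bg = background - selection
        other = [pos[c] for c in cell_ids if c in bg]
    if not other:
        raise QueryError("comparison group is empty (selection covers "
                         "all cells or background is contained in it)")
    return ViolinComparison(
        gene_id=gene_id,
        group_a=GroupStats.from_values(vec[sel_idx]),
        group_b=GroupStats.from_values(vec[other]),
        background_overlap_removed=overlap,
    )


# ---------------------------------------------------------------------------
# cluster heatmap


@dataclass
class ClusterHeatmap:
    """Per-cluster mean expression of an ordered gene list.

    ``matrix`` is |clusters| x |genes|; with per-gene scaling each gene
    column is mapped to (v - min) / (max - min), constant columns to 0.
    """

    cluster_labels: list[str]
    gene_ids: list[str]
    matrix: np.ndarray
    summary: str = "mean"
    scaling: str = "none"  # none | per-gene

    def to_tsv(self) -> str:
        lines = ["cluster\t" + "\t".join(self.gene_ids)]
        for label, row in zip(self.cluster_labels, self.matrix):
            lines.append(label + "\t"
                         + "\t".join(format(float(v), ".6g") for v in row))
        return "\n".join(lines) + "\n"


def cluster_means(store: MatrixStore, cluster_field: MetaField,
                  cell_ids: list[str], genes: list[str],
                  scaling: str = "none",
                  log: BuildLog | None = None) -> ClusterHeatmap:
    """Mean expression of each gene within each cluster.

    Cluster labels are ordered by their categorical codes (descending cell
    count). Unknown genes are skipped with a warning so a curated list with a
    stale symbol still yields a heatmap.
    """
    if cluster_field.kind != CATEGORICAL:
        raise QueryError(f"cluster field {cluster_field.name!r} must be "
                         f"categorical, got {cluster_field.kind}")
    if scaling not in ("none", "per-gene"):
        raise QueryError(f"unknown scaling {scaling!r}")
    labels = sorted(cluster_field.value_dict,
                    key=lambda v: cluster_field.value_dict[v])
    codes = cluster_field.codes()
    members = [np.nonzero(codes == cluster_field.value_dict[lab])[0]
               for lab in labels]

    kept: list[str] = []
    cols: list[np.ndarray] = []
    for g in genes:
        if g not in store:
            if log is not None:
                log.warn(f"heatmap gene {g!r} not in matrix; skipped")
            continue
        vec = fetch_gene(store, g).astype(np.float64)
        cols.append(np.array([vec[m].mean() if m.size else 0.0 for m in members]))
        kept.append(g)
    matrix = (np.column_stack(cols) if cols
              else np.zeros((len(labels), 0)))
    if scaling == "per-gene" and matrix.size:
        lo = matrix.min(axis=0, keepdims=True)
        hi = matrix.max(axis=0, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(span > 0, (matrix - lo) / np.where(span > 0, span, 1),
                              0.0)
        matrix = scaled
    return ClusterHeatmap(labels, kept, matrix, summary="mean", scaling=scaling)
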