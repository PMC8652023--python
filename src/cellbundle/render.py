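"""Headless figure generation: scatter, split scatter, violin, heatmap.

Every renderer writes an image (SVG is the deterministic reference; PNG is
supported) *and* returns a machine-readable render report — point counts per
color, legend entries, axis ranges, the statistics drawn — which is also
written as a JSON sidecar next to the image. Tests assert on the report,
never on pixels: font rasterization and antialiasing are not reproducible
across platforms, but the numbers behind the figure are.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from ._util import dump_json
from .annotate import CATEGORICAL, MISSING_COLOR, assign_colors, \
    discretize_expression
from .bundle import OpenBundle
from .matrix_store import fetch_gene
from .query import ClusterHeatmap, ViolinComparison

plt.rcParams["svg.hashsalt"] = "cellbundle"  # deterministic SVG ids

DEFAULT_POINT_SIZE = 6.0
DEFAULT_FIGSIZE = (6.0, 6.0)


@dataclass
class RenderSpec:
    """What to draw: one layout, one color source (metadata field OR gene)."""

    layout: str | None = None
    field: str | None = None
    gene: str | None = None
    palette: str | None = None
    point_size: float = DEFAULT_POINT_SIZE
    selection: set | None = None  # cell ids to outline
    n_bins: int | None = None

    def __post_init__(self) -> None:
        if (self.field is None) == (self.gene is None):
            raise ValueError("exactly one of field/gene must be set")


def _xy_digest(coords: np.ndarray) -> str:
    return hashlib.sha256(
        np.round(coords, 6).astype("<f8").tobytes()).hexdigest()


def _scatter_payload(bundle: OpenBundle, spec: RenderSpec):
    """Resolve a spec into per-cell colors + a legend block + a report."""
    layout = bundle.layout(spec.layout)
    if spec.gene is not None:
        vec = fetch_gene(bundle.store, spec.gene)
        n_bins = spec.n_bins or bundle.manifest["defaults"]["n_bins"]
        palette = spec.palette or bundle.manifest["defaults"][
            "palette_expression"]
        legend, bins = discretize_expression(vec, n_bins=n_bins,
                                             palette=palette)
        colors = [legend.bin_colors[b] for b in bins]
        legend_entries = [
            {"label": lab, "color": col, "count": cnt}
            for lab, col, cnt in zip(legend.labels(), legend.bin_colors,
                                     legend.bin_counts)]
        title = spec.gene
    else:
        f = bundle.field(spec.field)
        if f.kind == CATEGORICAL:
            palette = spec.palette or bundle.manifest["defaults"][
                "palette_categorical"]
            cmap = assign_colors(f, palette)
            colors = [cmap[v] for v in f.values]
            legend_entries = [
                {"label": v, "color": cmap[v], "count": f.counts[v]}
                for v in f.value_dict]
        else:
            if f.legend is None:
                raise ValueError(f"field {spec.field!r} has no legend")
            colors = [f.legend.bin_colors[b] for b in f.bins]
            legend_entries = [
                {"label": lab, "color": col, "count": cnt}
                for lab, col, cnt in zip(f.legend.labels(),
                                         f.legend.bin_colors,
                                         f.legend.bin_counts)]
        title = spec.field

    per_color: dict[str, int] = {}
    for c in colors:
        per_color[c] = per_color.get(c, 0) + 1
    report = {
        "title": title,
        "layout": layout.name,
        "n_points": len(colors),
        "legend": legend_entries,
        "per_color_counts": per_color,
        "xy_digest": _xy_digest(layout.coords),
        "axis_ranges": {
            "x": [float(layout.coords[:, 0].min()),
                  float(layout.coords[:, 0].max())],
            "y": [float(layout.coords[:, 1].min()),
                  float(layout.coords[:, 1].max())],
        },
        "n_selected": (len(spec.selection & set(layout.cell_ids))
                       if spec.selection else 0),
    }
    return layout, colors, legend_entries, report


def _draw_scatter(ax, layout, colors, spec: RenderSpec) -> None:
    ax.scatter(layout.coords[:, 0], layout.coords[:, 1], s=spec.point_size,
               c=colors, linewidths=0)
    if spec.selection:
        mask = np.array([c in spec.selection for c in layout.cell_ids])
        if mask.any():
            ax.scatter(layout.coords[mask, 0], layout.coords[mask, 1],
                       s=spec.point_size * 2, facecolors="none",
                       edgecolors="black", linewidths=0.6)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")


def _legend_text(entries) -> str:
    return "\n".join(f"{e['label']}: {e['count']}" for e in entries[:20])


def _finish(fig, out, report: dict) -> dict:
    out = Path(out)
    fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)
    dump_json(report, str(out) + ".json")
    return report


def render_scatter(bundle: OpenBundle, spec: RenderSpec, out) -> dict:
    """One point per cell at its layout position, colored by the spec's
    field or gene; the legend lists categories/bins with their counts."""
    layout, colors, legend_entries, report = _scatter_payload(bundle, spec)
    fig, ax = plt.subplots(figsize=DEFAULT_FIGSIZE)
    _draw_scatter(ax, layout, colors, spec)
    ax.set_title(report["title"])
    ax.text(1.02, 1.0, _legend_text(legend_entries), transform=ax.transAxes,
            va="top", fontsize=7)
    fig.tight_layout()
    return _finish(fig, out, report)


def render_split(bundle: OpenBundle, spec_left: RenderSpec,
                 spec_right: RenderSpec, out) -> dict:
    """Side-by-side panes over the same layout with identical axis ranges,
    so a point sits at the same position in both panes."""
    left_layout, left_colors, left_legend, left_rep = _scatter_payload(
        bundle, spec_left)
    right_layout, right_colors, right_legend, right_rep = _scatter_payload(
        bundle, spec_right)
    fig, (axl, axr) = plt.subplots(1, 2, figsize=(11, 5.5),
                                   sharex=True, sharey=True)
    _draw_scatter(axl, left_layout, left_colors, spec_left)
    _draw_scatter(axr, right_layout, right_colors, spec_right)
    axl.set_title(left_rep["title"])
    axr.set_title(right_rep["title"])
    xs = np.concatenate([left_layout.coords[:, 0], right_layout.coords[:, 0]])
    ys = np.concatenate([left_layout.coords[:, 1], right_layout.coords[:, 1]])
    for ax in (axl, axr):
        ax.set_xlim(float(xs.min()), float(xs.max()))
        ax.set_ylim(float(ys.min()), float(ys.max()))
    fig.tight_layout()
    shared = {"x": [float(xs.min()), float(xs.max())],
              "y": [float(ys.min()), float(ys.max())]}
    report = {"left": left_rep, "right": right_rep, "shared_axes": shared}
    return _finish(fig, out, report)


def render_violin(comparison: ViolinComparison, out,
                  labels: tuple[str, str] = ("selection", "rest")) -> dict:
    """Two distributions side by side with quartile marks; group sizes are
    printed in the axis labels. A group too small (or too flat) for a density
    estimate degrades to a stick at its value range."""
    fig, ax = plt.subplots(figsize=(4.5, 5))
    groups = [comparison.group_a, comparison.group_b]
    for i, g in enumerate(groups, start=1):
        if g.cell_count >= 2 and g.max > g.min:
            ax.violinplot([g.values], positions=[i], showextrema=False)
        else:
            ax.plot([i, i], [g.min, g.max], color="C0", lw=4)
            ax.plot(i, g.min, marker="o", color="C0")
        ax.plot([i - 0.1, i + 0.1], [g.median, g.median], color="black")
        ax.plot([i, i], [g.q1, g.q3], color="black", lw=2)
    ax.set_xticks([1, 2])
    ax.set_xticklabels([f"{labels[0]}\n(n={groups[0].cell_count})",
                        f"{labels[1]}\n(n={groups[1].cell_count})"])
    ax.set_ylabel(comparison.gene_id)
    fig.tight_layout()
    report = {
        "gene": comparison.gene_id,
        "groups": [
            {"label": lab, "cell_count": g.cell_count, "mean": g.mean,
             "median": g.median, "q1": g.q1, "q3": g.q3,
             "min": g.min, "max": g.max}
            for lab, g in zip(labels, groups)
        ],
        "background_overlap_removed": comparison.background_overlap_removed,
    }
    return _finish(fig, out, report)


def render_heatmap(hm: ClusterHeatmap, out) -> dict:
    """Clusters on the y axis, genes on the x axis, tile color from the
    (scaled) per-cluster mean."""
    if not hm.cluster_labels or not hm.gene_ids:
        raise ValueError("empty heatmap")
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.4 * len(hm.gene_ids) + 2),
                 max(2.5, 0.4 * len(hm.cluster_labels) + 1.5)))
    im = ax.imshow(hm.matrix, aspect="auto", cmap="Reds",
                   vmin=0 if hm.scaling == "per-gene" else None)
    ax.set_xticks(range(len(hm.gene_ids)))
    ax.set_xticklabels(hm.gene_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(hm.cluster_labels)))
    ax.set_yticklabels(hm.cluster_labels, fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    report = {
        "clusters": hm.cluster_labels,
        "genes": hm.gene_ids,
        "scaling": hm.scaling,
        "summary": hm.summary,
        "values": [[float(v) for v in row] for row in hm.matrix],
    }
    return _finish(fig, out, report)
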