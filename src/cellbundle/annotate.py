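"""Field typing, expression discretization, and color assignment.

Every coloring mode in the viewer reduces to one of two machines:

* a **categorical** field: values mapped to integer codes (descending count
  order, ties lexicographic) and colored by cycling a qualitative palette;
* an **expression legend**: a numeric vector cut into ordered bins, each bin
  mapped to a color sampled from a light-to-dark sequential ramp, highest bin
  darkest.

Single-cell matrices are strongly zero-inflated, so the default
discretization reserves bin 0 for exact zeros and distributes the remaining
bins over the positive values by quantile. Missing metadata values become an
explicit "(missing)" category colored gray rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import BuildLog

MISSING_MARKERS = ("", "NA", "NaN")
MISSING_LABEL = "(missing)"
MISSING_COLOR = "#b0b0b0"

CATEGORICAL = "categorical"
NUMERIC = "numeric"
UNIQUE_ID = "uniqueId"

DEFAULT_N_BINS = 10


# ---------------------------------------------------------------------------
# palettes

# ColorBrewer-style hex sets; qualitative sets cycle, sequential ramps are
# sampled light -> dark so the highest expression bin lands on the dark end.
PALETTES: dict[str, dict] = {
    "tab20": {
        "kind": "qualitative",
        "colors": [
            "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
            "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
            "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
            "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
        ],
    },
    "paired": {
        "kind": "qualitative",
        "colors": [
            "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99",
            "#e31a1c", "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a",
            "#ffff99", "#b15928",
        ],
    },
    "reds": {
        "kind": "sequential",
        "colors": [
            "#fff5f0", "#fee0d2", "#fcbba1", "#fc9272", "#fb6a4a",
            "#ef3b2c", "#cb181d", "#a50f15", "#67000d",
        ],
    },
    "blues": {
        "kind": "sequential",
        "colors": [
            "#f7fbff", "#deebf7", "#c6dbef", "#9ecae1", "#6baed6",
            "#4292c6", "#2171b5", "#08519c", "#08306b",
        ],
    },
    "viridis": {
        "kind": "sequential",
        "colors": [
            "#fde725", "#b5de2b", "#6ece58", "#35b779", "#1f9e89",
            "#26828e", "#31688e", "#3e4989", "#482878", "#440154",
        ],
    },
}

DEFAULT_QUALITATIVE = "tab20"
DEFAULT_SEQUENTIAL = "reds"


class PaletteError(KeyError):
    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:
        return (f"unknown palette {self.name!r}; "
                f"available: {', '.join(sorted(PALETTES))}")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    return tuple(int(h[i:i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]


def _rgb_to_hex(rgb: Sequence[float]) -> str:
    return "#%02x%02x%02x" % tuple(int(round(c)) for c in rgb)


def sample_ramp(palette_name: str, n: int) -> list[str]:
    """n colors evenly spaced along a sequential ramp; last = darkest end."""
    pal = PALETTES.get(palette_name)
    if pal is None:
        raise PaletteError(palette_name)
    anchors = [np.array(_hex_to_rgb(c), dtype=float) for c in pal["colors"]]
    if n == 1:
        return [_rgb_to_hex(anchors[-1])]
    out = []
    for i in range(n):
        t = i / (n - 1) * (len(anchors) - 1)
        lo = int(np.floor(t))
        hi = min(lo + 1, len(anchors) - 1)
        frac = t - lo
        out.append(_rgb_to_hex(anchors[lo] * (1 - frac) + anchors[hi] * frac))
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MetaField:
    """One typed metadata column.

    For categorical fields ``value_dict`` maps value -> integer code, codes
    0..K-1 in descending count order (ties lexicographic); ``counts`` holds
    per-value cell counts. Numeric fields keep a float array with NaN for
    missing entries. ``color_map`` is filled by :func:`assign_colors`.
    """

    name: str
    kind: str
    values: list[str]
    value_dict: dict[str, int] | None = None
    counts: dict[str, int] | None = None
    numeric: np.ndarray | None = None
    color_map: dict[str, str] | None = None
    legend: "ExpressionLegend | None" = None
    bins: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def codes(self) -> np.ndarray:
        if self.kind != CATEGORICAL or self.value_dict is None:
            raise ValueError(f"field {self.name!r} is not categorical")
        return np.array([self.value_dict[_norm_missing(v)] for v in self.values])


@dataclass
class ExpressionLegend:
    """Discretization of a numeric vector into ordered color bins.

    ``breaks`` has ``n_bins + 1`` strictly ascending boundaries. When
    ``zero_bin`` is set, bin 0 holds exact zeros only and ``breaks[0]`` is 0.
    ``bin_counts`` always sums to the number of cells discretized.
    """

    breaks: list[float]
    n_bins: int
    bin_colors: list[str]
    bin_counts: list[int]
    zero_bin: bool

    def labels(self) -> list[str]:
        out = []
        for b in range(self.n_bins):
            if b == 0 and self.zero_bin:
                out.append("0")
            else:
                out.append(f"{self.breaks[b]:g}–{self.breaks[b + 1]:g}")
        return out


# ---------------------------------------------------------------------------
# field typing


def _norm_missing(v: str) -> str:
    return MISSING_LABEL if v in MISSING_MARKERS else v


def _parse_number(v: str) -> float | None:
    try:
        x = float(v)
    except ValueError:
        return None
    return x


def infer_field_kind(name: str, raw_values: list[str]) -> MetaField:
    """Classify a raw text column.

    numeric if every non-missing value parses as a number; uniqueId if all
    values are distinct and non-numeric; categorical otherwise. Missing
    markers ("", "NA", "NaN") are counted as their own "(missing)" category
    (categorical) or NaN (numeric). Always classifies; never raises.
    """
    if not raw_values:
        raise ValueError(f"field {name!r} has no values")
    non_missing = [v for v in raw_values if v not in MISSING_MARKERS]
    parsed = [_parse_number(v) for v in non_missing]
    if non_missing and all(p is not None for p in parsed):
        numeric = np.array([
            np.nan if v in MISSING_MARKERS else float(v) for v in raw_values
        ])
        return MetaField(name, NUMERIC, list(raw_values), numeric=numeric)
    if (len(set(raw_values)) == len(raw_values)
            and len(raw_values) == len(non_missing)):
        return MetaField(name, UNIQUE_ID, list(raw_values))
    normed = [_norm_missing(v) for v in raw_values]
    counts: dict[str, int] = {}
    for v in normed:
        counts[v] = counts.get(v, 0) + 1
    ordered = sorted(counts, key=lambda v: (-counts[v], v))
    value_dict = {v: i for i, v in enumerate(ordered)}
    return MetaField(name, CATEGORICAL, normed,
                     value_dict=value_dict,
                     counts={v: counts[v] for v in ordered})


def type_table(cells) -> list[MetaField]:
    """Type every column of a CellTable; field 0 (the id column) is uniqueId
    by construction."""
    fields = []
    for i, name in enumerate(cells.field_names):
        f = infer_field_kind(name, cells.columns[name])
        if i == 0:
            f.kind = UNIQUE_ID
            f.value_dict = None
            f.counts = None
            f.numeric = None
        fields.append(f)
    return fields


# ---------------------------------------------------------------------------
# discretization


def discretize_expression(vector, n_bins: int = DEFAULT_N_BINS,
                          strategy: str = "quantile",
                          palette: str = DEFAULT_SEQUENTIAL,
                          log: BuildLog | None = None,
                          ) -> tuple[ExpressionLegend, np.ndarray]:
    """Cut a non-negative finite vector into ordered bins.

    When zeros are present, bin 0 holds exactly the zeros and the remaining
    bins partition the positive values by the chosen strategy; quantile bins
    target near-equal occupancy (ties collapse duplicate breaks, shrinking
    the bin count, which is logged). Returns the legend and a per-cell bin
    index array. A constant vector collapses to a single bin with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if strategy not in ("quantile", "linear"):
        raise ValueError(f"unknown strategy {strategy!r}")
    v = np.asarray(vector, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("vector contains non-finite values")

    all_nonneg = float(v.min()) >= 0.0
    zero_mask = v == 0.0
    use_zero_bin = bool(all_nonneg and zero_mask.any())
    pos = v[~zero_mask] if use_zero_bin else v

    # degenerate: nothing but zeros, or a constant vector
    if pos.size == 0 or float(pos.min()) == float(pos.max()):
        if pos.size == 0:  # all zeros
            legend = ExpressionLegend([0.0, 0.0], 1, sample_ramp(palette, 1),
                                      [int(v.size)], zero_bin=True)
            legend.breaks = [0.0]
            _finalize_single(legend)
            if log is not None:
                log.warn("all-zero vector: single-bin legend")
            return legend, np.zeros(v.size, dtype=int)
        if use_zero_bin:
            # zeros plus one repeated positive value -> two bins
            c = float(pos[0])
            colors = sample_ramp(palette, 2)
            legend = ExpressionLegend([0.0, c, c], 2, colors,
                                      [int(zero_mask.sum()), int(pos.size)],
                                      zero_bin=True)
            return legend, (~zero_mask).astype(int)
        if log is not None:
            log.warn(f"constant vector (value {float(pos[0]):g}): "
                     f"single-bin legend")
        legend = ExpressionLegend([float(pos[0]), float(pos[0])], 1,
                                  sample_ramp(palette, 1), [int(v.size)],
                                  zero_bin=False)
        return legend, np.zeros(v.size, dtype=int)

    k_target = n_bins - 1 if use_zero_bin else n_bins
    s = np.sort(pos)
    n = s.size
    if strategy == "quantile":
        interior = [float(s[(i * n) // k_target]) for i in range(1, k_target)]
    else:
        edges = np.linspace(float(s[0]), float(s[-1]), k_target + 1)
        interior = [float(e) for e in edges[1:-1]]
    # strictly ascending, strictly inside (min, max)
    dedup: list[float] = []
    for b in interior:
        if float(s[0]) < b < float(s[-1]) and (not dedup or b > dedup[-1]):
            dedup.append(b)
    k_actual = len(dedup) + 1
    if k_actual < k_target and log is not None:
        log.warn(f"tied values collapsed quantile breaks: {k_actual} bins "
                 f"instead of {k_target}")

    # bins are (break[i-1], break[i]]: a value equal to a break goes below it
    pos_bins = np.searchsorted(np.array(dedup), pos, side="left")
    breaks_pos = [float(s[0])] + dedup + [float(s[-1])]

    if use_zero_bin:
        total_bins = k_actual + 1
        bins = np.zeros(v.size, dtype=int)
        bins[~zero_mask] = pos_bins + 1
        breaks = [0.0] + breaks_pos
    else:
        total_bins = k_actual
        bins = np.searchsorted(np.array(dedup), v, side="left")
        breaks = breaks_pos

    counts = np.bincount(bins, minlength=total_bins).astype(int).tolist()
    legend = ExpressionLegend(breaks, total_bins, sample_ramp(palette, total_bins),
                              counts, zero_bin=use_zero_bin)
    return legend, bins


def _finalize_single(legend: ExpressionLegend) -> None:
    legend.breaks = [0.0, 0.0]
    legend.n_bins = 1


# ---------------------------------------------------------------------------
# colors


def assign_colors(field_or_legend, palette_name: str | None = None):
    """Attach colors.

    Categorical MetaField: cycle a qualitative palette in code order; the
    "(missing)" category always gets gray. ExpressionLegend: sample the
    sequential ramp evenly, last bin = ramp end (darkest). Returns the
    color map (dict for fields, list for legends) and stores it on the input.
    """
    if isinstance(field_or_legend, ExpressionLegend):
        name = palette_name or DEFAULT_SEQUENTIAL
        if name not in PALETTES:
            raise PaletteError(name)
        colors = sample_ramp(name, field_or_legend.n_bins)
        field_or_legend.bin_colors = colors
        return colors

    f: MetaField = field_or_legend
    name = palette_name or DEFAULT_QUALITATIVE
    pal = PALETTES.get(name)
    if pal is None:
        raise PaletteError(name)
    if f.kind == CATEGORICAL:
        colors = pal["colors"]
        cmap = {}
        for value, code in f.value_dict.items():
            cmap[value] = (MISSING_COLOR if value == MISSING_LABEL
                           else colors[code % len(colors)])
        f.color_map = cmap
        return cmap
    raise ValueError(f"cannot color field {f.name!r} of kind {f.kind}; "
                     f"numeric fields are colored through their legend")


# ---------------------------------------------------------------------------
# histograms


def field_histogram(field: MetaField, subset: set[str] | None,
                    cell_ids: list[str]) -> dict[str, int]:
    """Distribution of a field over a cell subset.

    Categorical: per-value counts (all values present, zero-filled). Numeric:
    per-bin counts of the field's legend (computed on first use). Counts sum
    to the subset size; an empty subset yields all zeros.
    """
    if subset is None:
        mask = np.ones(len(cell_ids), dtype=bool)
    else:
        mask = np.array([c in subset for c in cell_ids])
    if field.kind == CATEGORICAL:
        hist = {v: 0 for v in field.value_dict}
        for i in np.nonzero(mask)[0]:
            hist[_norm_missing(field.values[i])] += 1
        return hist
    if field.kind == NUMERIC:
        if field.legend is None or field.bins is None:
            finite = np.nan_to_num(field.numeric, nan=0.0)
            field.legend, field.bins = discretize_expression(finite)
        hist = {label: 0 for label in field.legend.labels()}
        labels = field.legend.labels()
        for i in np.nonzero(mask)[0]:
            hist[labels[int(field.bins[i])]] += 1
        return hist
    raise ValueError(f"no histogram for field kind {field.kind}")
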