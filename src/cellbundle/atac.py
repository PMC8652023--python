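"""ATAC mode: peaks as matrix rows and "peaks near a gene" interval queries.

In ATAC datasets the matrix rows are open-chromatin intervals rather than
genes, identified as ``chrom:start-end`` (0-based, half-open, the BED
convention). Searching a gene then means: find the peaks within a window of
the gene's transcription start site (TSS) and color by them. The window is
anchored at the TSS — strand-aware, the standard regulatory-proximity
convention — with a 100 kb default.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path

from ._util import BuildLog, open_maybe_gzip

DEFAULT_WINDOW = 100_000

_PEAK_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class AtacError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Peak:
    """One open-chromatin interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AtacError(f"invalid peak interval {self.chrom}:{self.start}-"
                            f"{self.end} (need 0 <= start < end)")

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcript span; the TSS is the strand-aware 5' end."""

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AtacError(f"gene {self.symbol}: strand must be + or -, "
                            f"got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise AtacError(f"gene {self.symbol}: txStart {self.tx_start} "
                            f">= txEnd {self.tx_end}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def parse_peak_id(name: str) -> Peak:
    """Parse a matrix row name of the form ``chrom:start-end``."""
    m = _PEAK_ID_RE.match(name)
    if m is None:
        raise AtacError(f"row name {name!r} is not a chrom:start-end peak id")
    return Peak(m["chrom"], int(m["start"]), int(m["end"]))


def load_peaks(source, log: BuildLog | None = None) -> list[Peak]:
    """Load peaks from a BED3+ file path, or from an iterable of
    ``chrom:start-end`` row names. Output is sorted by (chrom, start, end);
    duplicate intervals are removed with a logged count."""
    peaks: list[Peak] = []
    if isinstance(source, (str, Path)):
        with open_maybe_gzip(source, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise AtacError(f"{source}: line {lineno} has fewer than "
                                    f"3 BED columns")
                try:
                    peak = Peak(parts[0], int(parts[1]), int(parts[2]))
                except (ValueError, AtacError) as exc:
                    raise AtacError(f"{source}: line {lineno}: {exc}") from None
                peaks.append(peak)
    else:
        for name in source:
            peaks.append(parse_peak_id(name))
    ordered = sorted(set(peaks))
    n_dup = len(peaks) - len(ordered)
    if n_dup and log is not None:
        log.warn(f"{n_dup} duplicate peak intervals removed")
        log.count("peaks.deduplicated", n_dup)
    return ordered


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from TSV (symbol, chrom, strand, txStart, txEnd);
    a header row is detected and skipped."""
    genes: list[GeneModel] = []
    with open_maybe_gzip(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise AtacError(f"{path}: line {lineno} has fewer than 5 columns")
            if lineno == 1 and not parts[3].isdigit():
                continue  # header
            genes.append(GeneModel(parts[0], parts[1], parts[2],
                                   int(parts[3]), int(parts[4])))
    return genes


def normalize_chrom(name: str) -> str:
    """Map the two dominant chromosome dialects onto one: "chr1" -> "1"."""
    return name[3:] if name.startswith("chr") else name


class PeakIndex:
    """Sorted peaks grouped by chromosome for binary-search lookups.

    Built once from a sorted peak list; ``overlapping`` locates candidates by
    bisection on start coordinates and scans only a local neighbourhood
    bounded by the longest peak on that chromosome — never the full list.
    """

    def __init__(self, peaks: list[Peak], normalize: bool = False):
        self.normalize = normalize
        self.by_chrom: dict[str, list[Peak]] = {}
        for p in peaks:
            key = normalize_chrom(p.chrom) if normalize else p.chrom
            self.by_chrom.setdefault(key, []).append(p)
        self._starts = {c: [p.start for p in ps] for c, ps in self.by_chrom.items()}
        self._max_len = {c: max(p.end - p.start for p in ps)
                         for c, ps in self.by_chrom.items()}

    def overlapping(self, chrom: str, qstart: int, qend: int) -> list[Peak]:
        key = normalize_chrom(chrom) if self.normalize else chrom
        peaks = self.by_chrom.get(key)
        if not peaks or qstart >= qend:
            return []
        starts = self._starts[key]
        hi = bisect_left(starts, qend)  # peaks with start < qend
        lo = bisect_left(starts, qstart - self._max_len[key])
        return [p for p in peaks[lo:hi] if p.end > qstart]


def peaks_near_gene(gene: GeneModel, peaks, window: int = DEFAULT_WINDOW,
                    normalize_chroms: bool = False) -> list[Peak]:
    """All peaks overlapping ``[tss - window, tss + window)`` on the gene's
    chromosome (clipped at 0), half-open overlap test, sorted output.

    ``peaks`` may be a sorted Peak list or a prebuilt :class:`PeakIndex`;
    passing the index amortizes the per-chromosome grouping across genes.
    """
    if window < 0:
        raise AtacError("window must be >= 0")
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(
        peaks, normalize=normalize_chroms)
    qstart = max(0, gene.tss - window)
    qend = gene.tss + window
    if window == 0:
        qend = gene.tss + 1  # the single TSS base
    return sorted(index.overlapping(gene.chrom, qstart, qend))
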