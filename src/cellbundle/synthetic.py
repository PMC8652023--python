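"""Seeded generator of complete fake single-cell datasets.

Emulates the structure the viewer exists to show — distinct cell clusters
with marker genes and well-separated 2D embedding blobs — without any
biological realism (no batch effects, trajectories or library-size
variation). Counts are drawn from a zero-inflated negative binomial: base
means per gene are log-normal, marker genes get a fold-change bump inside
their cluster, and an extra dropout keeps the matrix around 80% zeros so the
zero-bin discretization path is always exercised.

``generate`` writes every format the importers consume (MTX triple, dense
TSV, metadata, two layouts, dataset-genes list, a build config, BED peaks +
gene models for ATAC tests) plus a ground-truth record sufficient to predict
cluster means, violin statistics and histograms within sampling error. The
same seed always produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._util import dump_json
from .io_import import write_dense, write_mtx
from .model import CellTable, ExpressionMatrix, Layout


@dataclass
class SyntheticSpec:
    """Parameters of the simulated dataset; defaults give a small but
    structured dataset: 5 clusters, 4 markers each, 8x marker fold-change,
    ~80% zeros overall."""

    n_cells: int = 1000
    n_genes: int = 200
    n_clusters: int = 5
    markers_per_cluster: int = 4
    base_mean: float = 1.0        # log-normal median of per-gene means
    base_sigma: float = 0.6       # log-normal sigma of per-gene means
    dispersion: float = 1.5       # NB size parameter (var = mu + mu^2/size)
    dropout: float = 0.55         # extra zero inflation on top of NB zeros
    marker_fold_change: float = 8.0
    blob_sd: float = 1.0          # within-cluster layout spread
    blob_radius: float = 10.0     # cluster centers on a circle of this radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("markers_per_cluster x n_clusters exceeds n_genes")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    cluster_of_cell: dict[str, str]
    markers: dict[str, list[str]]          # cluster label -> marker gene ids
    blob_centers: dict[str, tuple[float, float]]
    gene_means: dict[str, dict[str, float]]  # cluster -> gene -> expected mean
    spec: SyntheticSpec = field(repr=False, default=None)


def _simulate(spec: SyntheticSpec):
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"GENE{i:03d}" for i in range(spec.n_genes)]
    accessions = [f"ENSG{i:08d}" for i in range(spec.n_genes)]
    cell_ids = [f"cell{i:04d}" for i in range(spec.n_cells)]
    clusters = [f"cluster{k + 1}" for k in range(spec.n_clusters)]

    assignment = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    base_mu = spec.base_mean * rng.lognormal(0.0, spec.base_sigma,
                                             size=spec.n_genes)

    markers: dict[str, list[str]] = {}
    marker_idx = rng.permutation(spec.n_genes)[: spec.markers_per_cluster
                                               * spec.n_clusters]
    for k, label in enumerate(clusters):
        sel = marker_idx[k * spec.markers_per_cluster:
                         (k + 1) * spec.markers_per_cluster]
        markers[label] = [gene_ids[i] for i in sorted(sel)]

    # per-gene, per-cluster expected mean (before dropout)
    mu = np.tile(base_mu[:, None], (1, spec.n_clusters))
    for k, label in enumerate(clusters):
        for g in markers[label]:
            mu[gene_ids.index(g), k] *= spec.marker_fold_change

    size = spec.dispersion
    counts = np.zeros((spec.n_genes, spec.n_cells), dtype=np.float32)
    for k in range(spec.n_clusters):
        cols = np.nonzero(assignment == k)[0]
        if cols.size == 0:
            continue
        m = mu[:, k][:, None]
        p = size / (size + m)
        draw = rng.negative_binomial(size, p, size=(spec.n_genes, cols.size))
        keep = rng.random((spec.n_genes, cols.size)) >= spec.dropout
        counts[:, cols] = (draw * keep).astype(np.float32)

    # layout: cluster centers evenly on a circle, Gaussian blobs around them
    angles = 2 * np.pi * np.arange(spec.n_clusters) / spec.n_clusters
    centers = np.column_stack([spec.blob_radius * np.cos(angles),
                               spec.blob_radius * np.sin(angles)])
    coords = centers[assignment] + rng.normal(0, spec.blob_sd,
                                              size=(spec.n_cells, 2))
    # a second, rotated layout so layout switching is exercised
    theta = np.pi / 5
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    coords2 = coords @ rot.T

    ages = rng.integers(20, 71, size=spec.n_cells)
    labels = [clusters[a] for a in assignment]

    gene_means = {
        label: {g: float(mu[i, k]) * (1 - spec.dropout)
                for i, g in enumerate(gene_ids)}
        for k, label in enumerate(clusters)
    }
    truth = GroundTruth(
        cluster_of_cell=dict(zip(cell_ids, labels)),
        markers=markers,
        blob_centers={lab: (float(c[0]), float(c[1]))
                      for lab, c in zip(clusters, centers)},
        gene_means=gene_means,
        spec=spec,
    )
    return (gene_ids, accessions, cell_ids, counts, labels, ages,
            coords, coords2, truth, rng)


def make_dataset(spec: SyntheticSpec):
    """In-memory variant of :func:`generate`: returns (matrix, cells,
    layouts, dataset_genes, truth) without touching disk."""
    (gene_ids, accessions, cell_ids, counts, labels, ages,
     coords, coords2, truth, _rng) = _simulate(spec)
    aliases = {a: g for a, g in zip(accessions, gene_ids)}
    matrix = ExpressionMatrix(gene_ids, cell_ids, counts, aliases)
    cells = CellTable(
        cell_ids=list(cell_ids),
        field_names=["cellId", "cluster", "age"],
        columns={"cellId": list(cell_ids), "cluster": labels,
                 "age": [str(int(a)) for a in ages]},
    )
    layouts = [Layout("tsne", list(cell_ids), coords),
               Layout("umap", list(cell_ids), coords2)]
    dataset_genes = [g for label in sorted(truth.markers)
                     for g in truth.markers[label]]
    return matrix, cells, layouts, dataset_genes, truth


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def generate(spec: SyntheticSpec, out_dir) -> GroundTruth:
    """Write the full fixture tree for one synthetic dataset.

    Files: mtx/ (matrix.mtx, features.tsv, barcodes.tsv), exprMatrix.tsv,
    meta.tsv, tsne.tsv, umap.tsv, quickGenes.txt, cellbundle.conf,
    peaks.bed, genes.tsv, ground_truth.json, synthetic_spec.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, cells, layouts, dataset_genes, truth = make_dataset(spec)
    (gene_ids, accessions, cell_ids) = (matrix.gene_ids,
                                        [a for a in matrix.aliases],
                                        matrix.cell_ids)

    write_mtx(matrix, out_dir / "mtx", accessions=accessions)
    write_dense(matrix, out_dir / "exprMatrix.tsv")
    _write_tsv(out_dir / "meta.tsv", cells.field_names,
               zip(*(cells.columns[n] for n in cells.field_names)))
    for layout in layouts:
        _write_tsv(out_dir / f"{layout.name}.tsv", ["cell", "x", "y"],
                   ((c, format(x, ".6f"), format(y, ".6f"))
                    for c, (x, y) in zip(layout.cell_ids, layout.coords)))
    (out_dir / "quickGenes.txt").write_text(
        "".join(g + "\n" for g in dataset_genes), encoding="utf-8")

    _write_atac_fixture(spec, out_dir)

    (out_dir / "cellbundle.conf").write_text(
        "\n".join([
            'name="synthetic"',
            'shortLabel="Synthetic test dataset"',
            'matrix="mtx"',
            'meta="meta.tsv"',
            'coords=["tsne.tsv:tSNE", "umap.tsv:UMAP"]',
            'clusterField="cluster"',
            'quickGenes="quickGenes.txt"',
            f'nBins={10}',
        ]) + "\n", encoding="utf-8")

    dump_json({
        "cluster_of_cell": truth.cluster_of_cell,
        "markers": truth.markers,
        "blob_centers": {k: list(v) for k, v in truth.blob_centers.items()},
    }, out_dir / "ground_truth.json")
    dump_json(asdict(spec), out_dir / "synthetic_spec.json")
    return truth


def _write_atac_fixture(spec: SyntheticSpec, out_dir: Path) -> None:
    """Seeded random peaks + gene models on a small fake genome, written as
    BED and TSV for the proximity-query tests."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    chroms = ["chr1", "chr2", "chr3"]
    chrom_len = 10_000_000
    n_peaks, n_genes = 500, 20
    peaks = []
    for _ in range(n_peaks):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, chrom_len - 2000))
        length = int(rng.integers(150, 1500))
        peaks.append((chrom, start, start + length))
    peaks.sort()
    with open(out_dir / "peaks.bed", "w", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end in peaks:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    rows = []
    for i in range(n_genes):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, chrom_len - 100_000))
        rows.append((f"ATGENE{i:02d}", chrom,
                     "+" if rng.random() < 0.5 else "-",
                     start, start + int(rng.integers(1_000, 80_000))))
    _write_tsv(out_dir / "genes.tsv",
               ["symbol", "chrom", "strand", "txStart", "txEnd"], rows)
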