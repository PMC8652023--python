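# cellbundle

Build and query **self-contained static bundles** for single-cell expression
data.

Single-cell RNA-seq (and ATAC-seq) analyses end with an expression matrix,
per-cell metadata (cluster labels, age, donor, ...) and one or more 2D
embeddings (tSNE, UMAP). Sharing that result interactively usually means
running a compute server. `cellbundle` takes the other route: it compiles a
dataset into a directory of plain static files — a per-gene random-access
compressed expression store, typed metadata with color assignments,
coordinate tables, a cluster heatmap and a JSON manifest — from which every
interactive operation of a single-cell viewer can be answered with nothing
but file reads:

- coloring cells by any metadata field or by any gene's expression,
- switching layouts and side-by-side (split) comparison,
- "Find Cells" conjunctive metadata filtering and cell-id export,
- violin comparison of a gene in a selection vs. background cells,
- the clusters × dataset-genes mean-expression heatmap,
- metadata histograms over a selection,
- ATAC mode: peaks-near-gene TSS proximity queries.

It is a library first (`import cellbundle`), with a thin `scb` CLI, and is
aimed at people who build or test such viewers, or who want the viewer's
computations as deterministic, scriptable functions.

## The core machinery

**Per-gene store.** For genes *g₁…g_G* over *N* cells in a fixed canonical
order, each per-cell vector *x_g* ∈ ℝ^N is stored as
deflate(float32-LE(*x_g*)), concatenated in gene order into
`exprMatrix.bin`; a JSON sidecar maps *g* → (offset, length, CRC32).
Fetching one gene is one seek + one read of its block — I/O is bounded by
the block, not the matrix — which is what lets a static file server (HTTP
range requests) or this library serve single genes from arbitrarily large
matrices.

**Expression binning.** Single-cell counts are zero-inflated, so coloring
uses a dedicated zero bin: bin 0 = {i : x_i = 0}, and the positive values
are partitioned into the remaining *k* − 1 bins by quantile (near-equal
occupancy; tied quantile breaks collapse and shrink the bin count). Bin *j*
gets the *j*-th color of a light→dark sequential ramp, so the highest bin
is darkest. Categorical fields are coded 0…K−1 by descending cell count
(ties lexicographic) and colored by cycling a qualitative palette.

**Aggregations.** The heatmap entry for cluster *c* and gene *g* is the
mean of *x_g* over cells of *c*, optionally scaled per gene to
(v − min)/(max − min). Violin comparisons report n, mean, median, Q1/Q3
(linear interpolation), min, max for the selection and for the background
(or all remaining cells). ATAC "peaks near a gene" returns all peaks
overlapping [TSS − w, TSS + w) — TSS strand-aware, intervals 0-based
half-open, default w = 100 kb — via binary search on sorted peaks.

All of it is deterministic: the same inputs produce byte-identical bundles.

## Worked example

`examples/` contains one short script per capability. From
`examples/02_color_by_gene.py` (build a 300-cell synthetic dataset, fetch a
marker gene from the store, discretize it):

```
gene GENE000: 300 cells, 184 zeros, max 58
bin  range          cells  color
  0  0                184  #fff5f0
  1  1–2               46  #fcbba1
  2  2–3               18  #fb6a4a
  3  3–7               25  #cb181d
  4  7–58              27  #67000d
```

184 zero-count cells land in the dedicated zero bin; the 116 expressing
cells split into four quantile bins whose counts sum with the zeros to all
300 cells, and the top bin (7–58 counts) is the darkest red. From
`examples/03_select_export_violin.py`, filtering to `cluster1 AND age
25–60` and comparing a cluster-1 marker against the rest:

```
selected 72 cells (cluster1, age 25-60); exported 72 ids to selected.txt
selection: n=72   mean=  7.06 median= 0.0 IQR=[0, 11]
     rest: n=228  mean=  1.66 median= 0.0 IQR=[0, 2]
```

The marker was simulated with an 8× within-cluster fold change, and the
selection mean sits ~4× above the background mean (dropout keeps both
medians at 0 — typical of sparse counts).

## CLI

```bash
scb synth -o data --seed 1                 # synthetic dataset + config
scb build -c data/cellbundle.conf -o out   # compile the bundle
scb validate out                           # integrity report
scb query gene out GENE000                 # cell<TAB>value
scb query cells out -f cluster=cluster1 -f "age=30..50"
scb query violin out GENE001 -f cluster=cluster1
scb query heatmap out                      # clusters x dataset-genes TSV
scb query peaks out ATGENE00 --window 50000
scb collection -r tree.json -o site       # hierarchical index files
```

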