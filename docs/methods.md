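# Methods

## Scope and data model

The package turns three inputs — a gene × cell expression matrix, a
per-cell metadata table, and one or more 2D embedding coordinate tables —
into a static *bundle* from which viewer operations are answered without a
server. The unit of work is the `Dataset`: matrix, metadata and layouts
reordered to one *canonical cell order*, defined as the matrix column order
restricted to the intersection of the three cell-id sets. Cells missing
from any source are dropped and counted in the build log (counts per source
sum to source size minus canonical size); an empty intersection is an
error, because in practice it means an identifier-convention mismatch, not
disjoint data. Matching is exact string equality; an opt-in
`strip_suffix` removes one trailing `-<digits>` barcode suffix and nothing
fuzzier — silent fuzzy matching hides data bugs.

Values are stored as float32 and must be non-negative and finite; the
importers reject negatives rather than clamping, since negative expression
indicates a wrong input (e.g. a scaled residual matrix) rather than
something to repair. Duplicate gene ids are suffixed `_2`, `_3`, … in input
order and logged — never summed — so every input row remains individually
retrievable. Two-column features files (accession + symbol) display the
symbol and keep the accession as an alias resolved at lookup time; aliases
are persisted in the bundle manifest rather than the store index so that
stores built from alias-free formats (dense TSV) are byte-identical to
stores built from alias-carrying ones.

## Store format

`exprMatrix.bin` concatenates one block per gene, in gene order: the
zlib/deflate compression (fixed level 6) of the little-endian float32 cell
vector. `exprMatrix.json` carries, per gene, `[offset, length, crc32]`
plus an encoding descriptor: format version, value type, compression,
`n_cells`, and a SHA-256 digest of the canonical cell-id list. The digest
is checked against the bundle manifest at open time to detect
matrix/metadata drift. The index lives in a sidecar, not embedded, so a
plain HTTP range request on the data file can serve any single gene. The
format is original to this package and versioned in the index document.
Float32 round trips are lossless by construction
(decode(encode(v)) = float32(v)); an optional lossy uint16 encoding was
considered and deliberately not implemented — correctness first, and no
current user needs the size win.

## Field typing and discretization

Metadata columns are classified from their raw text: *numeric* if every
non-missing value parses as a number, *uniqueId* if all values are distinct
and non-numeric, otherwise *categorical*. The missing markers are the empty
string, `NA` and `NaN`; missing values become an explicit `(missing)`
category colored gray (categorical) or NaN (numeric) — visible, never
silently dropped. Categorical codes are assigned by descending cell count
with lexicographic tie-break, which keeps legends stable across runs and
puts the dominant population first.

Expression vectors (and non-negative numeric metadata) are discretized with
a dedicated zero bin whenever zeros are present: bin 0 holds exactly the
zeros, and the remaining *k* − 1 of the *k* requested bins (default
*k* = 10) partition the positive values. The default strategy is quantile:
interior break *i* is the sorted positive value at rank ⌊i·n/k⌋, and a
value equal to a break is assigned below it, so occupancies match the
sort-and-split partition within ±1 when values are distinct. Duplicate
breaks produced by heavily tied data are collapsed, shrinking the bin count
with a logged warning — a correct coarse legend beats a fixed bin count
with empty or overlapping bins. A constant vector collapses to a single
bin. The `linear` strategy uses equal-width bins over the positive range
instead. Rationale for the zero bin: typical single-cell matrices here are
~80% zeros, and quantiles over the raw vector would waste most bins on
zero.

Colors: categorical fields cycle a qualitative palette (built-ins of 12 and
20 colors) in code order; legends sample a light→dark sequential ramp
(piecewise-linear interpolation in RGB between anchor colors) evenly, so
the highest bin always receives the ramp's dark endpoint.

## Queries

Selection queries are conjunctions of predicates (`equals`, `in`, closed
`range`, `gt`, `lt`); categorical operators compare decoded values, numeric
operators parsed numbers, and applying a numeric operator to a categorical
field is a type error rather than an empty result. Disjunction is out of
scope by design — every added filter narrows the selection, matching the
mental model of a filter panel.

Violin comparisons report per-group n, mean, median, quartiles, min and
max. Quartiles use the linear-interpolation convention (numpy's default),
pinned in the manifest because quartile conventions differ across languages
and the numbers must be reproducible elsewhere. Background cells
overlapping the selection are removed from the background with a logged
count (a loose background is a UI reality, not an error); an empty
comparison group after removal is an error. Values are reported exactly as
stored — any log or other transform is the caller's decision.

Cluster heatmaps average each requested gene within each cluster; per-gene
scaling maps a gene's cluster means to (v − min)/(max − min) with constant
genes at 0. Unknown genes in a curated list are skipped with a warning so a
stale symbol does not kill the display.

## ATAC proximity

Peaks are 0-based half-open intervals, identified as `chrom:start-end`
(parseable back to coordinates), sorted by (chrom, start, end) and
deduplicated with a logged count. "Near a gene" means overlapping
[TSS − w, TSS + w) on the gene's chromosome (clipped at 0; w = 0 degenerates
to the single TSS base), with the TSS strand-aware: `txStart` on +,
`txEnd` − 1 on −. The anchor and the 100 kb default are the package's
choice of the standard regulatory-proximity convention, recorded in the
bundle manifest. Lookup is binary search on per-chromosome start arrays
with a local scan bounded by the chromosome's longest peak. Chromosome
names match exactly by default; an opt-in normalization maps the
`chr1`/`1` dialects onto each other.

## Bundles and collections

The config dialect is flat `key=value` with quoted strings and bracketed
lists — deliberately not a general-purpose language, so it stays portable.
Required keys: `name`, `matrix`, `meta`, at least one `coords` entry;
unknown keys warn. The build pipeline is import → align → type/color →
store → layouts → metadata → heatmap → manifest, and is fully
deterministic: gzip members carry mtime 0 and no filename, JSON is written
with fixed formatting, nothing embeds a timestamp, so identical inputs give
byte-identical bundles. The manifest (`dataset.json`) is a single document
carrying labels, field dictionaries and legends, layout and file
checksums, dataset genes, ATAC parameters, aliases, format version and the
cell-order digest — one fetch bootstraps a viewer.

Validation re-derives what it can from the files alone: index offsets must
tile the data file exactly, sampled genes must decode to `n_cells` values
with matching CRCs, legend and category counts must sum to `n_cells`,
layout files must list exactly the canonical cells, and all digests must
agree. Failures are findings in a report, not exceptions, so one run lists
everything wrong. A corrupted block is caught either by the size/offset
check or the per-block CRC32; undetectable flips would require a CRC
collision within an unchanged length.

Collections are trees of named nodes (unique sibling names, leaves
referencing built bundle directories). Each internal node becomes an
`index.json`; the hierarchy reconstructs losslessly from the root index.
The tree model is minimal by design — nothing in the target use case needs
more than names, labels and nesting.

## Rendering

Renderers (scatter, split scatter, violin, heatmap) draw with matplotlib
(SVG reference output, PNG supported) and return a machine-readable render
report — per-color point counts, legend entries with counts, axis ranges, a
digest of the plotted coordinates, the statistics drawn — written as a JSON
sidecar. The report, never the pixels, is the test surface: font
rasterization and antialiasing are not stable across platforms, but the
numbers behind a figure are. Split panes share axis limits so positions
correspond between panes. Degenerate violin groups (n = 1 or zero spread)
are drawn as a stick rather than a density. Styling constants (point size
6 pt, figure sizes) are documented defaults, not contracts.

## Synthetic data

The generator emulates exactly the structure the viewer displays: `K`
clusters (default 5) with `m` marker genes each (default 4), negative
binomial counts with per-gene log-normal base means (median 1.0, σ = 0.6),
NB size 1.5, an 8× marker fold change inside the marker's cluster, and an
extra dropout of 0.55 that, combined with NB zeros, puts the matrix near
80% zeros so the zero-bin path is always exercised. Layouts are Gaussian
blobs (σ = 1) around cluster centers on a circle of radius 10, plus a
rotated copy as a second layout; metadata adds a numeric age field and the
uniqueId cell id. All parameters are recorded beside the data
(`synthetic_spec.json`) and the ground truth (cluster assignment, marker
map, blob centers, expected per-cluster means) is returned and written, so
tests can predict cluster means, violin statistics and histograms within
sampling error. One seed drives everything; the same seed yields
byte-identical files.

What the generator does **not** emulate: library-size variation, batch
effects, trajectories/doublets, realistic gene–gene correlation. Passing
tests therefore demonstrate correctness of the mechanics (storage,
binning, filtering, aggregation, proximity queries) on zero-inflated
clustered data, not robustness to every artifact of real experiments.

## Problem sizes and numerical choices

The standard test dataset is 1000 cells × 200 genes with 5 clusters —
large enough that quantile bins, cluster means and filter queries are
non-trivial, small enough that the whole suite re-simulates it freely.
Aggregation oracles are compared at 1e-6 absolute (float32 storage, float64
accumulation); store round trips and cross-format builds are compared at
tolerance 0 because the integer-valued counts are exactly representable in
float32 across MTX, TSV, h5ad and Loom. Ties in quantile breaks, the
closed-range filter convention, code-order tie-breaks and the
value-below-break bin assignment are all pinned above; degenerate inputs
(empty selections, constant vectors, all-zero genes, single-cell groups)
have defined, tested behavior.

## Known limitations

- The matrix is densified in memory during import; bundles are built from
  datasets that fit in RAM (the store, not the build, is the
  random-access path).
- No on-the-fly normalization or marker discovery: the store serves
  exactly the values it was given, and statistics are descriptive only.
- Loom support covers the conventional layout (`/matrix` genes × cells,
  `Gene`/`CellID` attributes, paired coordinate columns); exotic Loom
  attribute schemes are rejected with the available names listed.
- Seurat `.rds` files are not parsed; export to one of the four supported
  formats first.
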