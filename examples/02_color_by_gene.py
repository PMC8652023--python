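"""Color cells by a gene: fetch one expression vector and bin it.

Fetching reads only that gene's compressed block from the store (an O(1)
lookup in the index, one seek, one read). The vector is then discretized:
exact zeros get their own bin — single-cell matrices are mostly zeros — and
the positive values are split into quantile bins, each mapped to a ramp
color, darkest = highest.
"""

import tempfile
from pathlib import Path

import cellbundle as cb

work = Path(tempfile.mkdtemp(prefix="cellbundle-example-"))
spec = cb.SyntheticSpec(n_cells=300, n_genes=60, n_clusters=3, seed=42)
cb.generate(spec, work / "inputs")
cb.build_dataset(cb.parse_config(work / "inputs" / "cellbundle.conf"),
                 work / "bundle")

bundle = cb.open_bundle(work / "bundle")
gene = bundle.manifest["dataset_genes"][0]
vector = cb.fetch_gene(bundle.store, gene)
legend, bins = cb.discretize_expression(vector, n_bins=5)

print(f"gene {gene}: {vector.size} cells, "
      f"{(vector == 0).sum()} zeros, max {vector.max():g}")
print("bin  range          cells  color")
for i, (label, count, color) in enumerate(
        zip(legend.labels(), legend.bin_counts, legend.bin_colors)):
    print(f"{i:>3}  {label:<13} {count:>6}  {color}")
# Bin 0 holds exactly the zero-count cells; the remaining bins hold roughly
# equal numbers of the expressing cells, and the last color is the dark
# end of the ramp (highest expression).
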