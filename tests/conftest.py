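import pathlib

import pytest

import cellbundle as cb
from cellbundle.bundle import DatasetConfig, build_dataset

# one moderately sized dataset shared across modules; session-scoped so the
# simulation and build run once
STANDARD_SPEC = cb.SyntheticSpec(n_cells=1000, n_genes=200, n_clusters=5,
                                 markers_per_cluster=4, seed=1)


@pytest.fixture(scope="session")
def synthetic_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("synthetic")
    cb.generate(STANDARD_SPEC, d)
    return d


@pytest.fixture(scope="session")
def dataset():
    """In-memory (matrix, cells, layouts, dataset_genes, truth) tuple."""
    return cb.make_dataset(STANDARD_SPEC)


@pytest.fixture(scope="session")
def built_bundle(synthetic_dir, tmp_path_factory) -> pathlib.Path:
    out = tmp_path_factory.mktemp("bundle") / "synthetic"
    cfg = cb.parse_config(synthetic_dir / "cellbundle.conf")
    cfg.atac = {"peaks": "peaks.bed", "gene_models": "genes.tsv",
                "window": 100_000}
    build_dataset(cfg, out)
    return out


@pytest.fixture(scope="session")
def bundle(built_bundle):
    return cb.open_bundle(built_bundle)
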