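import numpy as np
import pandas as pd
import pytest

import floraseq as fs


@pytest.fixture(scope="session")
def small_config():
    return fs.SimConfig(n_genes=400, seed=7)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, small_config):
    """A complete synthetic fixture directory shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = fs.make_fixture(small_config, outdir)
    return paths


@pytest.fixture(scope="session")
def sim_data(small_config):
    """Counts plus ground truth, with both term catalogs generated so the
    planted-term record is populated (same seed path as fixture_bundle)."""
    cm, truth = fs.generate_counts(small_config)
    fs.generate_term_catalog(truth, small_config, kind="GO")
    fs.generate_term_catalog(truth, small_config, kind="pathway")
    return cm, truth


def toy_count_matrix(counts, lengths, meta_rows):
    """Build a CountMatrix from plain lists.

    ``counts``: dict sample_id -> list of ints; ``lengths``: list of bp;
    ``meta_rows``: list of (sample_id, sex, organ, stage, replicate).
    """
    genes = [f"g{i}" for i in range(len(lengths))]
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "sex", "organ", "stage", "replicate"]
    ).set_index("sample_id")
    return fs.CountMatrix(
        counts=counts_df.astype(np.int64),
        gene_lengths=pd.Series(lengths, index=counts_df.index, dtype=np.int64),
        samples=meta.loc[counts_df.columns],
    )


@pytest.fixture
def make_cm():
    return toy_count_matrix
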