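import numpy as np
import pytest

from pleoscore import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced synthetic dataset shared across tests."""
    return synthetic.gen_dataset(n_per_score=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    """The small dataset written to disk (tiles/, masks/, truth.csv)."""
    outdir = tmp_path_factory.mktemp("synthdata")
    synthetic.write_dataset(small_dataset, outdir)
    labels = small_dataset.truth[["tile", "score"]]
    labels.to_csv(outdir / "labels.csv", index=False)
    return outdir
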