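import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels6():
    """Two-group labels for a 3 + 3 design."""
    return np.array(["healthy"] * 3 + ["disease"] * 3)


@pytest.fixture
def small_dataset():
    """A tiny simulated dataset with 20% contamination, fixed seed."""
    from robustde import contaminate, simulate_counts

    data = simulate_counts(G=200, n_de=20, n1=3, n2=3, seed=42)
    return contaminate(data, 0.2, seed=43)


@pytest.fixture
def count_files(tmp_path):
    """Write a small count matrix + labels pair to disk, return the paths."""
    from robustde import simulate_counts
    from robustde.io import write_table

    data = simulate_counts(G=50, n_de=10, n1=3, n2=3, seed=7)
    counts_path = tmp_path / "counts.tsv"
    labels_path = tmp_path / "labels.tsv"
    counts = data.counts.reset_index(names="gene_id")
    counts.to_csv(counts_path, sep="\t", index=False)
    import pandas as pd

    pd.DataFrame({"sample_id": data.counts.columns, "group": data.labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    return counts_path, labels_path, data
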