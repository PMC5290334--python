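import numpy as np
import pandas as pd
import pytest

from mirisk.preprocess import (
    drop_superabundant,
    filter_robust,
    quotient_normalize,
    zscore_reference,
)
from mirisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced three-group cohort with two planted markers."""
    cfg = CohortConfig(
        n_unaffected=12,
        n_nonprogressed=14,
        n_progressed=12,
        n_mirnas=60,
        planted=((5, -1, 1.5), (33, +1, 1.5)),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def normalized(small_cohort):
    """(z, metadata, two-class labels, samples) for the small cohort."""
    counts = small_cohort.counts
    robust = filter_robust(counts, min_total=0)
    kept, _ = drop_superabundant(counts.loc[robust])
    q = quotient_normalize(counts.loc[kept], top_k=20)
    z = zscore_reference(q, small_cohort.metadata)
    meta = small_cohort.metadata
    two = meta[meta["group"].isin(["nonprogressed", "progressed"])]
    samples = list(two["sample_id"])
    labels = (
        two.set_index("sample_id").loc[samples, "group"] == "progressed"
    ).to_numpy()
    return z, meta, labels, samples


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_counts(values, mirnas=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(values)
    mirnas = mirnas or [f"miR-{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=mirnas, columns=samples)
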