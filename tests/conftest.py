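import numpy as np
import pandas as pd
import pytest

from bowtie_grn.core_model import ExpressionTimeSeries, ScoredNetwork
from bowtie_grn.synthetic_data import PRESETS, make_bowtie_grn, simulate_timeseries


@pytest.fixture
def toy_timeseries():
    """5 genes x (4 timepoints x 2 replicates), deterministic values."""
    rng = np.random.default_rng(42)
    samples = []
    for rep in ("a", "b"):
        for t in range(4):
            samples.append({"sample": f"{rep}{t}", "timepoint": t, "replicate": rep, "condition": "wt"})
    meta = pd.DataFrame(samples).set_index("sample")
    values = pd.DataFrame(
        rng.normal(5, 1, size=(5, 8)),
        index=[f"g{i}" for i in range(5)],
        columns=meta.index,
    )
    return ExpressionTimeSeries(values, meta)


@pytest.fixture
def small_world():
    return make_bowtie_grn(**PRESETS["bowtie-small"], seed=4)


@pytest.fixture
def small_series(small_world):
    return simulate_timeseries(small_world, n_timepoints=20, n_replicates=3, noise_sd=0.2, seed=4)


@pytest.fixture
def toy_network():
    return ScoredNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")], scores=[0.9, 0.5, 0.1])
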