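import numpy as np
import pytest

from synscav import load_packaged_series, load_packaged_single_ic50s

# Mixture dose-response measurements (assay, ratio) -> (axis conc ug/mL, scavenging %).
DPPH_MIX = {
    "1:2": ([12.5, 25, 50, 100, 150], [7.14, 13.35, 23.72, 48.58, 70.09]),
    "1:1": ([12.5, 25, 50, 100, 150], [19.51, 26.38, 41.46, 66.86, 90.23]),
    "2:1": ([12.5, 25, 50, 100, 150], [8.08, 13.35, 23.78, 44.65, 66.76]),
}
ABTS_MIX = {
    "1:2": ([2.5, 5, 10, 20, 30], [3.53, 8.88, 16.00, 33.09, 49.36]),
    "1:1": ([2.5, 5, 10, 20, 30], [4.66, 11.53, 23.12, 46.29, 69.28]),
    "2:1": ([2.5, 5, 10, 20, 30], [3.92, 7.56, 17.67, 35.70, 53.86]),
}

# Single-compound IC50s (ug/mL), fixed inputs to the isobole stage.
SINGLE_IC50 = {"DPPH": {"A": 310.2, "B": 344.8}, "ABTS": {"A": 78.03, "B": 94.77}}


@pytest.fixture(scope="session")
def packaged_series():
    return load_packaged_series()


@pytest.fixture(scope="session")
def packaged_singles():
    return load_packaged_single_ic50s()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
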