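import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catres.encoding import build_table_from_tracks
from catres.synthetic import SyntheticSpec, generate_dataset

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """12 chains with strong planted signal (sigma = 0.8), in memory."""
    spec = SyntheticSpec(seed=11, n_chains=12, length_range=(50, 80),
                         catalytic_per_chain=2, signal_strength=0.8)
    records, tracks = generate_dataset(spec)
    tables = {cid: build_table_from_tracks(t) for cid, t in tracks.items()}
    return records, tracks, tables


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
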