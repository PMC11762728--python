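import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import divelev as dl

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

THREE_TIP = "((A:3,B:3):7,C:10);"


@pytest.fixture
def three_tip_tree():
    return dl.read_newick_string(THREE_TIP)


@pytest.fixture(scope="session")
def synth_data():
    """Small seeded dataset reused across tests (40 genera, 3 gradients)."""
    return dl.generate_dataset(seed=11, n_tips=40, n_gradients=3)


@pytest.fixture(scope="session")
def synth_result(synth_data):
    d = synth_data
    return dl.analyze(d.tree, d.genus_table(), d.records, d.calibration)


def random_chronogram(seed: int, n_tips: int = 20) -> dl.Chronogram:
    return dl.synth.simulate_chronogram(
        dl.SynthConfig(seed=seed, n_tips=n_tips, crown_age_ma=100.0)
    )
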