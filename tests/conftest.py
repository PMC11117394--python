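import numpy as np
import pandas as pd
import pytest

from pkabc.config import PipelineConfig, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Small but realistic pipeline configuration for end-to-end tests."""
    return PipelineConfig(
        seed=7, synth=SyntheticConfig(n_participants=40, n_iterates=5, seed=7)
    )


@pytest.fixture
def noise_free_cfg():
    """Noise-free measurements with censoring disabled (tiny LOD)."""
    return PipelineConfig(
        seed=11,
        synth=SyntheticConfig(
            n_participants=30, n_iterates=4, seed=11,
            measurement_noise_logsd=0.0, lod=1e-12,
        ),
    )


@pytest.fixture
def toy_records():
    """Three records with log10 distances 0.2, 0.7 and 1.3 from the measurement."""
    measured = 1e-6
    return pd.DataFrame(
        {
            "participant_id": ["A", "A", "B"],
            "iterate": [0, 1, 0],
            "predicted": [measured * 10**0.2, measured * 10**0.7, measured * 10**1.3],
            "measured": [measured] * 3,
            "exposure_day1": [1e-4, 2e-4, 3e-4],
        }
    )
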