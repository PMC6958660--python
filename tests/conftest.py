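import numpy as np
import pytest

from pcgscreen import synth
from pcgscreen.framing import build_dataset
from pcgscreen.io import PipelineConfig
from pcgscreen.pipeline import train_default_emissions


@pytest.fixture(scope="session")
def clean_recording():
    """One low-noise recording with 20 cycles (segmentation-friendly)."""
    cfg = synth.SynthConfig(n_cycles=20, snr_db=30.0, rng_seed=42)
    return synth.generate_recording(cfg)


@pytest.fixture(scope="session")
def emissions():
    """Emission model fitted on a small synthetic corpus with known paths."""
    return train_default_emissions(PipelineConfig(), seed=123)


@pytest.fixture(scope="session")
def small_dataset():
    """~100 normalized 1.6 s frames from 2 recordings per class (true onsets)."""
    base = synth.SynthConfig(n_cycles=14, snr_db=25.0, rng_seed=7)
    recs = synth.generate_dataset({c: 2 for c in ("normal", "HFpEF", "HFrEF")}, base)
    cfg = PipelineConfig(use_true_onsets=True)
    return build_dataset(recs, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
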