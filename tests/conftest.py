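import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))

import transferome as tf
from transferome.config import SimulationParams


@pytest.fixture(scope="session")
def small_pair() -> tf.TranscriptomePair:
    """20 ortholog genes of 300 bp at 5% divergence."""
    return tf.generate_transcriptome_pair(20, 300, 0.05, seed=101)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(
        n_genes=20,
        transcript_length=300,
        read_length=50,
        fragment_length=120,
        library_size=2000,
    )


@pytest.fixture(scope="session")
def indexes(small_pair):
    return {
        "human": tf.TranscriptomeIndex(small_pair.records("human"), "human"),
        "mouse": tf.TranscriptomeIndex(small_pair.records("mouse"), "mouse"),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
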