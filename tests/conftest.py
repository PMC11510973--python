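import numpy as np
import pytest
from hypothesis import settings

from neurofuse.graphs import build_dataset
from neurofuse.synth import SynthConfig, gen_dataset

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_pairs():
    """Four one-minute segments (2 NM / 2 MS) for fast structural tests."""
    cfg = SynthConfig(n_segments_nm=2, n_segments_ms=2, segment_len=60.0,
                      seed=11)
    return gen_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_samples(tiny_pairs):
    return build_dataset(tiny_pairs, modalities=("beta", "fnirs", "fused:beta"))


@pytest.fixture(scope="session")
def study_pairs():
    """The full study-scale dataset: 61 NM + 75 MS five-minute segments."""
    return gen_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def study_samples(study_pairs):
    """Study-scale graph samples, keyed by modality."""
    samples = build_dataset(study_pairs,
                            modalities=("beta", "fnirs", "fused:beta"))
    return {
        "beta": [s for s in samples if s.modality == "beta"],
        "fnirs": [s for s in samples if s.modality == "fNIRS"],
        "fused": [s for s in samples if s.modality == "fused:beta"],
    }


def random_binary_graph(rng: np.random.Generator, n: int,
                        p: float) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
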