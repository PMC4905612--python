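import numpy as np
import pytest

from periscan.features import FeatureSet, MotifMatrix

ECOLI_G = 4_641_652  # E. coli K-12 chromosome length (bp)


@pytest.fixture(scope="session")
def strong_motif() -> MotifMatrix:
    """A 10-bp high-information motif (88 % consensus base per column)."""
    rng = np.random.default_rng(42)
    probs = np.full((10, 4), 0.04)
    probs[np.arange(10), rng.integers(0, 4, 10)] = 0.88
    return MotifMatrix(probs)


@pytest.fixture()
def small_feature_set() -> FeatureSet:
    return FeatureSet.from_positions([100, 5_000, 9_000], 10_000)
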