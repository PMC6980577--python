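import numpy as np
import pytest

from afdetect.features import FeatureConfig
from afdetect.rr_io import Window
from afdetect.synthetic import Rhythm, RhythmGeneratorSpec, build_dataset


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def constant_window():
    return Window(np.full(60, 800.0))


@pytest.fixture(scope="session")
def small_dataset():
    """60 AF + 60 sinus + 30 bigeminy windows, fixed seeds."""
    specs = [
        RhythmGeneratorSpec(Rhythm.AF, 60, 1),
        RhythmGeneratorSpec(Rhythm.SINUS, 60, 2),
        RhythmGeneratorSpec(Rhythm.BIGEMINY, 30, 3),
    ]
    features, labels, windows = build_dataset(specs)
    return features, labels, windows
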