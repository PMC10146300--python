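import numpy as np
import pytest

from ojipstress.synthetic_data import default_presets
from ojipstress.transients import MarkerSet


@pytest.fixture(scope="session")
def presets():
    """The packaged study-calibrated presets, keyed by (strain, treatment)."""
    return {(p.strain, p.treatment): p for p in default_presets()}


@pytest.fixture
def hand_markers():
    """Marker set whose JIP parameters were hand-evaluated independently."""
    return MarkerSet(1000, 2200, 3000, 4200, 5000)


def random_valid_markers(rng: np.random.Generator) -> MarkerSet:
    """A random monotone marker set with strictly positive gaps."""
    f_o = rng.uniform(100.0, 2000.0)
    gaps = rng.uniform(0.05, 1.0, size=4)
    levels = f_o + np.cumsum(gaps) / gaps.sum() * rng.uniform(0.5, 4.0) * f_o
    return MarkerSet(f_o, *levels)
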