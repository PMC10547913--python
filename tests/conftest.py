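import numpy as np
import pytest

from pamfuse import Volume
from pamfuse.pipeline import (
    tune_fiber_diameter,
    two_focus_fiber_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def random_volume(rng):
    def make(shape=(8, 8, 8), spacing=(2.0, 2.0, 3.0)):
        return Volume(rng.random(shape), spacing=spacing)

    return make


@pytest.fixture(scope="session")
def tuned_diameter():
    """Fiber diameter whose mean single-focus DoF lands in 70-80 µm."""
    return tune_fiber_diameter()


@pytest.fixture(scope="session")
def noiseless_study(tuned_diameter):
    """Two-focus fiber protocol at defaults, no noise."""
    return two_focus_fiber_study(diameter_um=tuned_diameter)


@pytest.fixture(scope="session")
def noisy_study_15db(tuned_diameter):
    """Two-focus fiber protocol at 15 dB peak SNR (seed-controlled)."""
    return two_focus_fiber_study(diameter_um=tuned_diameter, snr_db=15.0, seed=1)


def preservation_excess(study):
    """Worst-case fused FWHM excess over the sharper single-focus FWHM.

    Scans every depth plane where the fused measurement is valid and at
    least one single-focus measurement is valid; returns the maximum of
    (fused FWHM - min valid single FWHM) in µm.
    """
    worst = -np.inf
    p1, p2, pf = (study.profiles[k] for k in ("focus1", "focus2", "fused"))
    for a, b, f in zip(p1, p2, pf):
        if not f.valid:
            continue
        singles = [p.value for p in (a, b) if p.valid]
        if not singles:
            continue
        worst = max(worst, f.value - min(singles))
    return worst
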