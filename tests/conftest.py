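"""Shared fixtures: fast sampling rate, planted profiles, analytic PSDs."""

import numpy as np
import pytest
from hypothesis import settings

from vibci.features import PSDVector
from vibci.simulate import make_subject_profile

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: Sampling rate used throughout the suite.  The simulator's SNR is
#: defined per frequency band, so results are insensitive to fs; 160 Hz
#: keeps the Monte-Carlo tests quick while satisfying the filter chain's
#: fs > 120 Hz requirement.
FS = 160.0

#: Planted-dominant gains: the (5, 9) couple at twice the amplitude of
#: the other candidates (amplitude SNR ~2 against the default background).
PLANTED_GAINS = {5: 4.0, 9: 4.0, 7: 2.0, 12: 2.0}
ZERO_GAINS = {5: 0.0, 7: 0.0, 9: 0.0, 12: 0.0}


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def planted_profile():
    return make_subject_profile(42, {"gains": PLANTED_GAINS})


@pytest.fixture
def zero_profile():
    return make_subject_profile(42, {"gains": ZERO_GAINS})


@pytest.fixture
def triangle_psd():
    """Factory for analytic triangular-peak PSDs on a fine grid.

    Returns (builder, resolution).  The builder places, on a flat
    baseline, triangular peaks of given apex height above the baseline
    and given base half-width, centered on grid points.
    """
    resolution = 0.025

    def build(peaks, baseline=0.0, lo=1.0, hi=30.0, resolution=resolution):
        freqs = np.arange(round(lo / resolution), round(hi / resolution) + 1)
        freqs = freqs * resolution
        power = np.full_like(freqs, baseline, dtype=float)
        for center, height, half_width in peaks:
            tri = height * np.clip(1.0 - np.abs(freqs - center) / half_width,
                                   0.0, None)
            power += tri
        return PSDVector(freqs, power, resolution)

    return build
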