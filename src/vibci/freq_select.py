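"""Subject-specific flicker-frequency selection by PSD peak scoring.

A candidate peak at frequency f is scored from the high-resolution PSD
of each screening epoch.  On each side of the peak, the prominence
Δp = M − m compares the maximum of the PSD in a close neighborhood of
the peak (±0.05 Hz) against the minimum in a larger one (±0.5 Hz); the
score is S = max(Δp₊, Δp₋) / ι with ι the width of the peak at half its
height.  Narrow, prominent peaks therefore score high; broad or absent
ones score low.  Per candidate the scores at f and its second harmonic
2f are summed over every screening repetition and over the occipital
electrodes, and the two best-scoring candidates — skipping pairs whose
harmonics collide — form the subject's frequency couple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import DEFAULT_HIGHRES_RESOLUTION, PSDVector, highres_psd
from .recording import (
    CANDIDATE_FREQS,
    OCCIPITAL_CHANNELS,
    Epoch,
    label_frequency,
)

CLOSE_HALF_WIDTH = 0.05  # Hz, neighborhood for the peak maximum
LARGE_HALF_WIDTH = 0.5   # Hz, neighborhood for the flank minimum
HARMONIC_TOL = 0.25      # Hz, default harmonic-collision tolerance


@dataclass(frozen=True)
class PeakScore:
    """All intermediate quantities of the peak score at one frequency."""

    f: float
    M_minus: float
    M_plus: float
    m_minus: float
    m_plus: float
    dp_minus: float
    dp_plus: float
    iota: float
    S: float


@dataclass(frozen=True)
class FrequencyCouple:
    """Ordered pair of selected flicker frequencies (Hz)."""

    f_low: float
    f_high: float

    def __post_init__(self):
        if not self.f_low < self.f_high:
            raise ValueError("couple must satisfy f_low < f_high")
        if self.f_low not in CANDIDATE_FREQS or self.f_high not in CANDIDATE_FREQS:
            raise ValueError("couple members must be candidate frequencies")

    def __iter__(self):
        return iter((self.f_low, self.f_high))


FrequencyScoreTable = dict[float, float]  # candidate Hz -> summed score


def _grid_window(psd: PSDVector, lo: float, hi: float) -> np.ndarray:
    if lo < psd.freqs[0] - 1e-9 or hi > psd.freqs[-1] + 1e-9:
        raise ValueError(
            f"window [{lo:.3f}, {hi:.3f}] Hz falls outside the PSD grid"
        )
    mask = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    return mask.nonzero()[0]

def _check_resolution(psd: PSDVector) -> None:
    if psd.resolution > CLOSE_HALF_WIDTH / 2 + 1e-12:
        raise ValueError(
            f"PSD grid spacing {psd.resolution:.4f} Hz too coarse for the "
            f"±{CLOSE_HALF_WIDTH:g} Hz close neighborhood"
        )


def side_delta(psd: PSDVector, f: float, side: str) -> tuple[float, float, float]:
    """One-sided peak prominence (M, m, Δp) at frequency ``f``.

    The left side uses the close window [f-0.05, f] and the large window
    [f-0.5, f]; the right side mirrors them.  Both windows share the
    center point, so Δp = M − m is never negative.
    """
    _check_resolution(psd)
    if side == "left":
        close = _grid_window(psd, f - CLOSE_HALF_WIDTH, f)
        large = _grid_window(psd, f - LARGE_HALF_WIDTH, f)
    elif side == "right":
        close = _grid_window(psd, f, f + CLOSE_HALF_WIDTH)
        large = _grid_window(psd, f, f + LARGE_HALF_WIDTH)
    else:
        raise ValueError("side must be 'left' or 'right'")
    M = float(psd.power[close].max())
    m = float(psd.power[large].min())
    return M, m, M - m


def half_height_width(psd: PSDVector, f: float) -> float:
    """Width ι (Hz) of the peak near ``f`` at half its apex height.

    The apex is the PSD maximum within ±0.05 Hz of f.  On each side the
    first crossing of apex/2, walking outward within ±0.5 Hz, is located
    by linear interpolation; a side with no crossing clamps at the
    window edge.  The result is floored at one grid step so degenerate
    single-bin peaks cannot produce a vanishing width.
    """
    _check_resolution(psd)
    close = _grid_window(psd, f - CLOSE_HALF_WIDTH, f + CLOSE_HALF_WIDTH)
    large = _grid_window(psd, f - LARGE_HALF_WIDTH, f + LARGE_HALF_WIDTH)
    apex_idx = close[np.argmax(psd.power[close])]
    apex = float(psd.power[apex_idx])
    if apex <= 0:
        return psd.resolution
    half = apex / 2.0

    freqs, power = psd.freqs, psd.power

    def crossing(direction: int, boundary: int) -> float:
        i = apex_idx
        while i != boundary:
            j = i + direction
            if power[j] < half:
                # linear interpolation between grid points i and j
                frac = (power[i] - half) / (power[i] - power[j])
                return float(freqs[i] + frac * (freqs[j] - freqs[i]))
            i = j
        return float(freqs[boundary])  # clamp at the window edge

    left = crossing(-1, large[0])
    right = crossing(+1, large[-1])
    return max(right - left, psd.resolution)


def peak_score(psd: PSDVector, f: float) -> PeakScore:
    """Score S = max(Δp₊, Δp₋) / ι of the candidate peak at ``f``."""
    M_minus, m_minus, dp_minus = side_delta(psd, f, "left")
    M_plus, m_plus, dp_plus = side_delta(psd, f, "right")
    iota = half_height_width(psd, f)
    return PeakScore(f=f, M_minus=M_minus, M_plus=M_plus,
                     m_minus=m_minus, m_plus=m_plus,
                     dp_minus=dp_minus, dp_plus=dp_plus, iota=iota,
                     S=max(dp_plus, dp_minus) / iota)


def score_candidates(step1_epochs: list[Epoch],
                     resolution: float = DEFAULT_HIGHRES_RESOLUTION,
                     candidates: tuple[float, ...] = CANDIDATE_FREQS,
                     ) -> FrequencyScoreTable:
    """Total peak score per candidate frequency from screening epochs.

    For each candidate f the scores at f and 2f are summed over all
    epochs of that stimulation class and over the occipital electrodes
    Oz, O1, O2.  Rest epochs do not contribute.
    """
    totals: FrequencyScoreTable = {f: 0.0 for f in candidates}
    scored = 0
    for epoch in step1_epochs:
        f = label_frequency(epoch.label)
        if f is None or f not in totals:
            continue
        for ch in OCCIPITAL_CHANNELS:
            psd = highres_psd(epoch.channel(ch), epoch.fs, resolution)
            totals[f] += peak_score(psd, f).S + peak_score(psd, 2 * f).S
        scored += 1
    if scored == 0:
        raise ValueError("no epochs labeled with a candidate stimulation frequency")
    return totals


def harmonic_conflict(f1: float, f2: float, tol: float = HARMONIC_TOL) -> bool:
    """True when the lower frequency's second harmonic hits the higher."""
    if f1 == f2:
        raise ValueError("frequencies must differ")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    lo, hi = sorted((f1, f2))
    return abs(2 * lo - hi) <= tol


def select_couple(table: FrequencyScoreTable,
                  tol: float = HARMONIC_TOL) -> FrequencyCouple:
    """Pick the two highest-scoring, harmonic-compatible candidates.

    Ties break toward the lower frequency.  If the runner-up's harmonic
    collides with the winner's, the next-best compatible candidate takes
    its place.
    """
    missing = set(CANDIDATE_FREQS) - set(table)
    if missing:
        raise ValueError(f"score table missing candidates {sorted(missing)}")
    ranked = sorted(table, key=lambda f: (-table[f], f))
    best = ranked[0]
    for other in ranked[1:]:
        if not harmonic_conflict(best, other, tol):
            return FrequencyCouple(*sorted((best, other)))
    raise ValueError("no harmonic-compatible couple among the candidates")
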