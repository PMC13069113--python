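"""Peak scoring (Δp, ι, S) against analytic fixtures and couple selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vibci.freq_select import (
    half_height_width,
    harmonic_conflict,
    peak_score,
    score_candidates,
    select_couple,
    side_delta,
)
from vibci.features import PSDVector
from vibci.preprocess import extract_epochs, filter_chain
from vibci.recording import ANALYSIS_CHANNELS
from vibci.simulate import ProtocolSpec, make_subject_profile, simulate_recording

from conftest import FS


class TestSideDelta:
    def test_flat_psd_has_zero_prominence(self, triangle_psd):
        psd = triangle_psd([], baseline=3.0)
        for side in ("left", "right"):
            M, m, dp = side_delta(psd, 9.0, side)
            assert (M, m, dp) == (3.0, 3.0, 0.0)

    def test_triangle_over_baseline_yields_its_height(self, triangle_psd):
        # base width 0.4 Hz -> half-width 0.2; the flank floor lies inside
        # the +-0.5 Hz window, so m recovers the baseline exactly.
        psd = triangle_psd([(9.0, 2.5, 0.2)], baseline=1.0)
        for side in ("left", "right"):
            M, m, dp = side_delta(psd, 9.0, side)
            assert M == pytest.approx(3.5)
            assert m == pytest.approx(1.0)
            assert dp == pytest.approx(2.5)

    def test_prominence_scales_linearly(self, triangle_psd):
        psd = triangle_psd([(9.0, 2.0, 0.2)], baseline=1.0)
        scaled = PSDVector(psd.freqs, 3.0 * psd.power, psd.resolution)
        _, _, dp = side_delta(psd, 9.0, "left")
        _, _, dp3 = side_delta(scaled, 9.0, "left")
        assert dp3 == pytest.approx(3.0 * dp)

    def test_window_outside_grid_rejected(self, triangle_psd):
        psd = triangle_psd([], lo=8.8, hi=9.2)
        with pytest.raises(ValueError, match="outside"):
            side_delta(psd, 9.0, "left")

    def test_coarse_grid_rejected(self):
        freqs = np.arange(3.0, 36.0, 0.5)
        with pytest.raises(ValueError, match="too coarse"):
            side_delta(PSDVector(freqs, np.ones_like(freqs), 0.5), 9.0, "left")


class TestHalfHeightWidth:
    def test_triangle_width_equals_base_half_width(self, triangle_psd):
        # apex h over zero baseline: half height is crossed halfway down
        # each flank, so the full width equals the base half-width w.
        for w in (0.1, 0.2, 0.4):
            psd = triangle_psd([(9.0, 2.0, w)])
            assert half_height_width(psd, 9.0) == pytest.approx(w, rel=1e-6)

    def test_peak_broader_than_window_clamps_to_one_hertz(self, triangle_psd):
        psd = triangle_psd([(9.0, 2.0, 3.0)], baseline=5.0)
        assert half_height_width(psd, 9.0) == pytest.approx(1.0)

    def test_width_invariant_under_scaling(self, triangle_psd):
        psd = triangle_psd([(9.0, 2.0, 0.3)])
        scaled = PSDVector(psd.freqs, 7.0 * psd.power, psd.resolution)
        assert half_height_width(scaled, 9.0) == pytest.approx(
            half_height_width(psd, 9.0))

    def test_zero_psd_floors_at_one_grid_step(self, triangle_psd):
        psd = triangle_psd([])
        assert half_height_width(psd, 9.0) == pytest.approx(psd.resolution)


class TestPeakScore:
    def test_flat_psd_scores_zero(self, triangle_psd):
        assert peak_score(triangle_psd([], baseline=2.0), 9.0).S == 0.0

    def test_score_is_amplitude_equivariant(self, triangle_psd):
        psd = triangle_psd([(9.0, 2.0, 0.2)])
        scaled = PSDVector(psd.freqs, 5.0 * psd.power, psd.resolution)
        assert peak_score(scaled, 9.0).S == pytest.approx(
            5.0 * peak_score(psd, 9.0).S)

    def test_narrow_peak_outscores_broad_peak_twofold(self, triangle_psd):
        w = 0.15
        psd = triangle_psd([(7.0, 2.0, w), (12.0, 2.0, 2 * w)])
        narrow = peak_score(psd, 7.0).S
        broad = peak_score(psd, 12.0).S
        assert narrow == pytest.approx(2.0 * broad, rel=1e-6)

    def test_halving_grid_resolution_changes_score_under_5pct(
            self, triangle_psd):
        coarse = triangle_psd([(9.0, 2.0, 0.2)], resolution=0.025)
        fine = triangle_psd([(9.0, 2.0, 0.2)], resolution=0.0125)
        s1, s2 = peak_score(coarse, 9.0).S, peak_score(fine, 9.0).S
        assert abs(s2 - s1) / s1 < 0.05


class TestHarmonicConflict:
    @pytest.mark.parametrize("f1,f2,expected", [
        (5.0, 10.0, True),
        (5.0, 9.0, False),
        (4.5, 9.0, True),
        (7.0, 12.0, False),
    ])
    def test_second_harmonic_collisions(self, f1, f2, expected):
        assert harmonic_conflict(f1, f2) is expected

    def test_candidate_set_is_conflict_free(self):
        from vibci.recording import CANDIDATE_FREQS
        for i, f1 in enumerate(CANDIDATE_FREQS):
            for f2 in CANDIDATE_FREQS[i + 1:]:
                assert not harmonic_conflict(f1, f2)

    @given(st.floats(4.0, 15.0), st.floats(4.0, 15.0))
    def test_symmetric_in_its_arguments(self, f1, f2):
        if f1 == f2:
            return
        assert harmonic_conflict(f1, f2) == harmonic_conflict(f2, f1)


class TestSelectCouple:
    def test_top_two_scores_win(self):
        assert tuple(select_couple({5: 10, 7: 1, 9: 8, 12: 2})) == (5, 9)

    def test_all_tied_breaks_toward_lower_frequencies(self):
        assert tuple(select_couple({5: 10, 7: 10, 9: 10, 12: 10})) == (5, 7)

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            select_couple({5: 1.0, 7: 2.0})


class TestScoreCandidates:
    def _screening_table(self, gains, seed):
        profile = make_subject_profile(0, {"gains": gains})
        p1 = ProtocolSpec.step_1()
        rec = simulate_recording(p1, profile, seed=seed, fs=FS)
        return score_candidates(extract_epochs(filter_chain(rec), p1))

    def test_planted_frequencies_get_top_scores(self):
        """Dominant 5/9 Hz gains win the score table (10-seed smoke)."""
        hits = 0
        for seed in range(10):
            table = self._screening_table({5: 4.0, 9: 4.0, 7: 2.0, 12: 2.0},
                                          seed)
            top2 = sorted(sorted(table, key=table.get, reverse=True)[:2])
            hits += top2 == [5.0, 9.0]
        assert hits >= 9

    def test_amplitude_scaling_leaves_the_selection_unchanged(
            self, planted_profile):
        """Scaling epochs by c scales totals by c^2 (power is quadratic
        in amplitude, the score linear in power) and never changes the
        selected couple."""
        p1 = ProtocolSpec.step_1()
        rec = simulate_recording(p1, planted_profile, seed=5, fs=FS)
        epochs = extract_epochs(filter_chain(rec), p1)
        table = score_candidates(epochs)
        for e in epochs:
            e.data *= 3.0
        scaled = score_candidates(epochs)
        for f in table:
            assert scaled[f] == pytest.approx(9.0 * table[f], rel=1e-9)
        assert tuple(select_couple(scaled)) == tuple(select_couple(table))

    def test_missing_occipital_channel_rejected(self, planted_profile):
        p1 = ProtocolSpec.step_1()
        channels = tuple(c for c in ANALYSIS_CHANNELS if c != "Oz")
        rec = simulate_recording(p1, planted_profile, seed=0, fs=FS,
                                 channel_labels=channels)
        with pytest.raises(KeyError, match="Oz"):
            score_candidates(extract_epochs(rec, p1))
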