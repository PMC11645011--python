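"""Fiducial detection stages and PTT feature extraction."""

import numpy as np
import pytest

from scalebp.errors import QualityError, ScalebpError
from scalebp.fiducials import (
    DEFAULT_PARAMS,
    ExtractionParams,
    compute_ptt,
    cycle_average,
    detect_fiducials,
    differentiate,
    extract_features,
    max_beats_per_segment,
    peak_threshold,
    relocate_candidates,
    truth_ipg_peaks,
    verify_extremum,
    zero_cross_extrema,
)
from scalebp.filters import Segment, segment_session
from scalebp.session import Calibration
from scalebp.simulate import SimulationConfig, simulate_session


class TestDifferentiate:
    def test_constant_gives_zeros(self):
        assert np.all(differentiate(np.full(10, 3.3)) == 0)

    def test_unit_ramp_gives_ones(self):
        d = differentiate(np.arange(10.0))
        assert d[0] == 0 and np.all(d[1:] == 1)

    def test_second_difference_of_square_is_two(self):
        n = np.arange(20.0)
        dd = differentiate(differentiate(n ** 2))
        assert np.all(dd[2:] == 2)

    def test_too_short_rejected(self):
        with pytest.raises(ScalebpError):
            differentiate([1.0])


class TestZeroCross:
    def test_peak_candidate_after_sign_change(self):
        assert zero_cross_extrema([1, 1, -1], "peak").tolist() == [2]

    def test_foot_candidate(self):
        assert zero_cross_extrema([-1, 1], "foot").tolist() == [1]

    def test_sinusoid_one_peak_one_foot_per_cycle(self):
        fs, f = 500.0, 1.0
        t = np.arange(int(3 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        d = differentiate(x)
        peaks = zero_cross_extrema(d, "peak")
        foots = zero_cross_extrema(d, "foot")
        assert len(peaks) == 3 and len(foots) == 3
        # analytic extrema at t = 0.25 + k and 0.75 + k seconds
        assert np.max(np.abs(peaks - (0.25 + np.arange(3)) * fs)) <= 1
        assert np.max(np.abs(foots - (0.75 + np.arange(3)) * fs)) <= 1


class TestThreshold:
    def test_mean_of_three_largest(self):
        assert peak_threshold([5, 3, 4, 1, 2], beta=1.0) == 4.0

    def test_all_equal(self):
        assert peak_threshold([2.0, 2.0, 2.0, 2.0], beta=0.7) == pytest.approx(1.4)

    def test_beta_scales(self):
        assert peak_threshold([8, 6, 4], beta=0.5) == 3.0

    def test_two_candidates_allowed(self):
        # a 2 s window at 60 BPM holds only two full cycles
        assert peak_threshold([4.0, 2.0], beta=1.0) == 3.0

    def test_too_few_candidates_is_quality_error(self):
        with pytest.raises(QualityError):
            peak_threshold([1.0], beta=1.0)

    def test_top3_mean_at_least_overall_mean(self, rng):
        for _ in range(50):
            amps = rng.uniform(0.1, 5.0, size=rng.integers(3, 30))
            assert peak_threshold(amps, beta=1.0) >= np.mean(amps) - 1e-12


class TestVerifyExtremum:
    def test_isolated_peak_accepted(self):
        x = np.concatenate([np.arange(30.0), np.arange(30.0)[::-1]])
        assert verify_extremum(x, 29, 25, "max") == 29

    def test_candidate_near_larger_peak_rejected(self):
        x = np.zeros(100)
        x[50] = 1.0
        x[60] = 2.0
        assert verify_extremum(x, 50, 25, "max") is None

    def test_plateau_earliest_wins(self):
        x = np.zeros(50)
        x[20:25] = 1.0
        assert verify_extremum(x, 20, 10, "max") == 20
        for i in range(21, 25):
            assert verify_extremum(x, i, 10, "max") is None

    def test_matches_bruteforce_definition(self, rng):
        # oracle: strict extremum of the clipped window, earliest tie wins
        for _ in range(200):
            x = rng.integers(0, 4, size=30).astype(float)
            idx = int(rng.integers(0, 30))
            hw = int(rng.integers(1, 8))
            lo, hi = max(0, idx - hw), min(len(x), idx + hw + 1)
            win = x[lo:hi]
            expect = idx if lo + int(np.argmax(win)) == idx else None
            assert verify_extremum(x, idx, hw, "max") == expect

    def test_relocation_lands_on_extremum(self):
        x = np.zeros(100)
        x[40] = 5.0
        assert relocate_candidates(x, [44], 10, "max").tolist() == [40]


class TestCycleAndTruthPeaks:
    def test_cycle_average_simple(self):
        assert cycle_average([100, 600, 1100]) == 500.0
        assert cycle_average([0, 250]) == 250.0

    def test_cycle_average_needs_two(self):
        with pytest.raises(QualityError):
            cycle_average([7])

    def test_close_pair_keeps_larger_amplitude(self):
        kept = truth_ipg_peaks([100, 350], [3.0, 5.0], cyc=500.0)
        assert kept.tolist() == [350]

    def test_exact_cycle_spacing_all_kept(self):
        kept = truth_ipg_peaks([0, 500, 1000], [1, 1, 1], cyc=500.0)
        assert kept.tolist() == [0, 500, 1000]

    def test_single_peak_kept(self):
        assert truth_ipg_peaks([42], [1.0], cyc=500.0).tolist() == [42]


class TestComputePTT:
    def test_fifty_samples_at_500hz_is_100ms(self):
        assert compute_ptt([300], [250], 500.0).tolist() == [100.0]

    def test_constant_offset_gives_constant_ptt(self):
        dp = np.array([300, 800, 1300])
        assert np.all(compute_ptt(dp, dp - 80, 500.0) == 160.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ScalebpError):
            compute_ptt([250], [300], 500.0)


class TestFullPipeline:
    def test_clean_segment_recovers_known_ptt(self, clean_segment, calibration):
        feats = extract_features(clean_segment, calibration)
        assert feats.quality_ok and feats.n_beats >= 1
        assert feats.ptt_free == pytest.approx(150.0, abs=2.0)
        assert feats.ptt_sys == pytest.approx(feats.ptt_free / 120.0)
        assert feats.ptt_dia == pytest.approx(feats.ptt_free / 80.0)

    def test_dipg_peak_before_ipg_peak(self, clean_segment):
        fid = detect_fiducials(clean_segment.bcg, clean_segment.ipg, 500.0)
        # steepest upstroke precedes the pulse peak on every paired beat
        for dp in fid.dipg_peaks:
            later_peaks = fid.ipg_peaks[fid.ipg_peaks > dp]
            assert len(later_peaks) > 0

    def test_ptt_positive_and_below_cycle(self, clean_segment):
        fid = detect_fiducials(clean_segment.bcg, clean_segment.ipg, 500.0)
        ptt = compute_ptt(fid.dipg_peaks, fid.bcg_peaks, 500.0)
        assert np.all(ptt > 0)
        assert np.all(ptt < fid.cycle_average * 1000.0 / 500.0)

    def test_flat_line_fails_quality(self, calibration):
        seg = Segment(np.zeros(1024), np.zeros(1024), 0, 500.0)
        feats = extract_features(seg, calibration)
        assert not feats.quality_ok and feats.n_beats == 0

    def test_amplitude_scale_invariance(self, clean_segment):
        fid1 = detect_fiducials(clean_segment.bcg, clean_segment.ipg, 500.0)
        fid2 = detect_fiducials(17.0 * clean_segment.bcg,
                                17.0 * clean_segment.ipg, 500.0)
        assert np.array_equal(fid1.dipg_peaks, fid2.dipg_peaks)
        assert np.array_equal(fid1.bcg_peaks, fid2.bcg_peaks)

    def test_time_shift_equivariance(self, clean_session):
        session, _ = clean_session
        k = 37
        a = detect_fiducials(session.bcg[1024:2048], session.ipg[1024:2048], 500.0)
        b = detect_fiducials(session.bcg[1024 + k:2048 + k],
                             session.ipg[1024 + k:2048 + k], 500.0)
        # interior beats present in both windows line up after the shift
        common = np.intersect1d(a.dipg_peaks, b.dipg_peaks + k)
        assert len(common) >= 1

    def test_high_rate_segment_holds_at_most_six_beats(self, calibration):
        cfg = SimulationConfig(
            duration_s=10.0, hr_start=200.0, hr_end=200.0, hrv_sd=0.0,
            bp_start=(120.0 + 1e-6, 80.0), bp_end=(120.0, 80.0),
            noise_sd=0.0, drift_amp=0.0, seed=2)
        session, _ = simulate_session(cfg)
        for seg in segment_session(session):
            feats = extract_features(seg, calibration)
            assert feats.n_beats <= 6

    def test_without_calibration_only_free_ptt(self, clean_segment):
        feats = extract_features(clean_segment, calibration=None)
        assert feats.ptt_free is not None
        assert feats.ptt_sys is None and feats.ptt_dia is None

    def test_max_beats_bound(self):
        assert max_beats_per_segment(1024, 500.0, 200.0) == 6
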