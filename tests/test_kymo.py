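"""Kymograph analysis: Gaussian frame fits, ON/OFF hysteresis, blink
counting, histograms and MSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kymoblink as kb
from kymoblink import kymo
from kymoblink.kymo import FrameFit, TrackFit


def gaussian_profile(n=40, amp=100.0, center=20.0, sigma=1.5, offset=10.0):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-((x - center) ** 2) / (2 * sigma**2)) + offset


class TestFitFrame:
    def test_noiseless_profile_recovers_parameters_exactly(self):
        f = kb.fit_frame(gaussian_profile())
        assert f.center_px == pytest.approx(20.0, abs=1e-6)
        assert f.sigma_px == pytest.approx(1.5, abs=1e-6)
        assert f.amplitude == pytest.approx(100.0, abs=1e-4)
        assert f.offset == pytest.approx(10.0, abs=1e-4)
        assert f.r2 > 0.999999

    def test_pure_noise_profiles_fit_poorly(self):
        # the study's empirical OFF signature: background-only frames fit
        # with R^2 < 0.7 in at least 95% of trials
        rng = np.random.default_rng(0)
        r2 = np.array(
            [kb.fit_frame(rng.normal(10.0, 3.0, 48)).r2 for _ in range(1000)]
        )
        assert np.mean(r2 < 0.7) >= 0.95

    def test_center_matches_simulator_ground_truth_without_noise(self):
        params = kb.KymoSimParams(background_sd=0.0, seed=21)
        km, truth = kb.simulate_kymograph(params)
        # rebuild a noiseless frame from the ground-truth position
        t = 10
        x = np.arange(params.n_pixels, dtype=float)
        clean = params.background_mean + params.photons_per_frame * np.exp(
            -((x - truth.true_positions_px[t]) ** 2) / (2 * params.psf_sigma_px**2)
        )
        f = kb.fit_frame(clean)
        assert f.center_px == pytest.approx(truth.true_positions_px[t], abs=1e-6)

    def test_constant_profile_r2_is_zero(self):
        f = kb.fit_frame(np.full(20, 7.0))
        assert f.r2 == 0.0

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            kb.fit_frame(np.array([1.0, 2.0, 3.0]))

    def test_subpixel_localization_precision_at_default_snr(self, default_kymo):
        km, truth = default_kymo
        track = kymo.fit_kymograph(km)
        on = truth.emitter_on.any(axis=0)
        err = (track.center_px - truth.true_positions_px)[on]
        assert np.std(err) < 0.5


class TestClassifyFrames:
    def test_all_high_r2_all_on(self):
        on = kb.classify_frames(np.full(10, 0.95))
        assert on.all()

    def test_clear_off_run(self):
        on = kb.classify_frames(np.array([0.95, 0.5, 0.5, 0.95]))
        assert on.tolist() == [True, False, False, True]

    def test_intermediate_band_inherits_preceding_state(self):
        on = kb.classify_frames(np.array([0.95, 0.8, 0.5, 0.95]))
        assert on.tolist() == [True, True, False, True]
        on2 = kb.classify_frames(np.array([0.95, 0.5, 0.8, 0.95]))
        assert on2.tolist() == [True, False, False, True]

    def test_leading_intermediates_take_first_resolved_state(self):
        on = kb.classify_frames(np.array([0.8, 0.8, 0.5, 0.95]))
        assert on.tolist() == [False, False, False, True]

    def test_all_intermediate_defaults_to_on(self):
        assert kb.classify_frames(np.full(5, 0.8)).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            kb.classify_frames(np.full(5, 0.8), r2_off=0.9, r2_on=0.7)

    @settings(derandomize=True, max_examples=50)
    @given(
        r2=st.lists(st.floats(0.0, 0.999), min_size=1, max_size=60),
        lower=st.floats(0.3, 0.69),
    )
    def test_lowering_off_threshold_never_adds_off_frames(self, r2, lower):
        r2 = np.array(r2)
        off_hi = (~kb.classify_frames(r2, r2_off=0.7, r2_on=0.9)).sum()
        off_lo = (~kb.classify_frames(r2, r2_off=lower, r2_on=0.9)).sum()
        assert off_lo <= off_hi


class TestCountBlinks:
    def test_all_on_no_blinks(self):
        assert kb.count_blinks(np.ones(10, dtype=bool)).n_blinks == 0

    def test_interior_off_runs_counted(self):
        s = kb.count_blinks(np.array([1, 0, 1, 0, 1], dtype=bool))
        assert s.n_blinks == 2
        assert [(e.start_frame, e.n_frames) for e in s.events] == [(1, 1), (3, 1)]

    def test_boundary_off_runs_censored(self):
        s = kb.count_blinks(np.array([0, 0, 1, 0, 1], dtype=bool))
        assert s.n_blinks == 1
        assert s.events[0].start_frame == 3

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError):
            kb.count_blinks(np.array([], dtype=bool))

    @settings(derandomize=True, max_examples=50)
    @given(
        state=st.lists(st.booleans(), min_size=1, max_size=40),
        pre=st.integers(0, 5),
        post=st.integers(0, 5),
    )
    def test_invariant_to_padding_with_on_frames(self, state, pre, post):
        inner = np.array(state, dtype=bool)
        padded = np.concatenate([np.ones(pre, bool), inner, np.ones(post, bool)])
        # padding with ON frames can only uncensor boundary runs, never
        # remove interior blinks
        n_inner = kb.count_blinks(inner).n_blinks
        n_padded = kb.count_blinks(padded).n_blinks
        assert n_padded >= n_inner
        # once both boundaries are ON, further padding changes nothing
        if pre >= 1 and post >= 1:
            more = np.concatenate([np.ones(3, bool), padded, np.ones(3, bool)])
            assert kb.count_blinks(more).n_blinks == n_padded


class TestBlinkHistogram:
    @staticmethod
    def _series(counts, duration=60.0):
        out = []
        for c in counts:
            state = np.ones(2 * c + 3, dtype=bool)
            state[1 : 2 * c + 1 : 2] = False  # c interior 1-frame blinks
            s = kb.count_blinks(state)
            s.duration_s = duration
            out.append(s)
        return out

    def test_all_zero_blinks(self):
        h = kb.blink_histogram(self._series([0] * 50))
        assert h.percent_at_n == {0: 100.0}
        assert h.n_kymographs == 50

    def test_percentages(self):
        h = kb.blink_histogram(self._series([1, 1, 2]))
        assert h.percent_at_n[1] == pytest.approx(200 / 3)
        assert h.percent_at_n[2] == pytest.approx(100 / 3)

    def test_mixed_durations_rejected(self):
        series = self._series([1], 60.0) + self._series([1], 30.0)
        with pytest.raises(ValueError):
            kb.blink_histogram(series)

    def test_counted_blinks_match_simulator_ground_truth(self):
        # oracle equivalence on a small batch (the full 200-kymograph check
        # runs with the acceptance suite)
        agree = 0
        for seed in range(20):
            km, truth = kb.simulate_kymograph(kb.KymoSimParams(seed=seed))
            track = kymo.fit_kymograph(km)
            on = kb.classify_frames(track)
            s = kb.count_blinks(on, frame_interval_s=km.frame_interval_s)
            agree += s.n_blinks == truth.true_blink_count
        assert agree >= 19


class TestTrackMsd:
    @staticmethod
    def _track(positions, r2=0.99, pixel_nm=63.2):
        frames = [FrameFit(p, 1.5, 100.0, 10.0, r2) for p in positions]
        return TrackFit(frames, pixel_nm=pixel_nm, frame_interval_s=0.1)

    def test_stationary_spot_msd_zero(self):
        msd = kb.track_msd(self._track(np.full(40, 12.0)))
        assert np.allclose(msd["msd_nm2"], 0.0)

    def test_diffusive_slope_recovers_step_variance(self):
        s2 = 0.2
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = np.concatenate([[0.0], np.cumsum(rng.normal(0, np.sqrt(s2), 199))])
            msd = kb.track_msd(self._track(pos))
            lags = msd["lag_frames"].to_numpy()[:5]
            A = np.vstack([lags, np.ones_like(lags)]).T
            slopes.append(
                np.linalg.lstsq(A, msd["msd_nm2"].to_numpy()[:5], rcond=None)[0][0]
            )
        expected = s2 * 63.2**2  # MSD(lag) = step_variance * lag
        assert np.mean(slopes) == pytest.approx(expected, rel=0.2)

    def test_too_few_on_frames_flagged_empty(self):
        msd = kb.track_msd(self._track(np.arange(5.0)))
        assert msd.empty
        assert msd.attrs["insufficient_on_frames"]

    def test_off_frames_excluded_from_pairs(self):
        pos = np.arange(20.0)
        track = self._track(pos)
        track.frames[5].r2 = 0.1  # one OFF frame
        msd = kb.track_msd(track)
        assert msd.loc[msd["lag_frames"] == 1, "n_pairs"].item() == 17
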