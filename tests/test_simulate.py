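"""Synthetic-data generators: determinism, degenerate cases, and convergence
of sampled frequencies to their analytic targets."""

import numpy as np
import pytest
from scipy import stats

import kymoblink as kb
from kymoblink import simulate
from kymoblink.simulate import KymoSimParams, MixtureSimParams


class TestSimulateKymograph:
    def test_identical_seeds_give_identical_output(self):
        k1, t1 = kb.simulate_kymograph(KymoSimParams(seed=3))
        k2, t2 = kb.simulate_kymograph(KymoSimParams(seed=3))
        np.testing.assert_array_equal(k1.intensity, k2.intensity)
        np.testing.assert_array_equal(t1.true_positions_px, t2.true_positions_px)
        assert t1.true_blink_count == t2.true_blink_count

    def test_zero_signal_zero_noise_is_flat_background(self):
        params = KymoSimParams(photons_per_frame=0.0, background_sd=0.0, seed=0)
        kymo, _ = kb.simulate_kymograph(params)
        np.testing.assert_array_equal(
            kymo.intensity, np.full_like(kymo.intensity, params.background_mean)
        )

    def test_no_blinking_gives_zero_true_blinks(self):
        _, truth = kb.simulate_kymograph(
            KymoSimParams(blink_rate_per_s=0.0, n_emitters=1, seed=1)
        )
        assert truth.true_blink_count == 0
        assert truth.emitter_on.all()

    def test_dimensions_and_walk_stay_in_bounds(self):
        params = KymoSimParams(seed=5, n_pixels=16, diffusion_coeff_px2_per_frame=2.0)
        kymo, truth = kb.simulate_kymograph(params)
        assert kymo.intensity.shape == (16, 600)
        assert truth.true_positions_px.min() >= 0.0
        assert truth.true_positions_px.max() <= 15.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            kb.simulate_kymograph(KymoSimParams(n_emitters=3))
        with pytest.raises(ValueError):
            kb.simulate_kymograph(KymoSimParams(n_pixels=3))
        with pytest.raises(ValueError):
            kb.simulate_kymograph(KymoSimParams(duration_s=-60))

    def test_two_emitters_blink_independently(self):
        # per-emitter dark fraction ~20%; joint darkness should match the
        # product of the marginals over a long record
        params = KymoSimParams(
            duration_s=2000.0,
            photons_per_frame=0.0,
            background_sd=0.0,
            n_emitters=2,
            blink_rate_per_s=-np.log(1 - 1 / 13) * 10.0,
            mean_dark_frames=3.0,
            seed=11,
        )
        _, truth = kb.simulate_kymograph(params)
        dark = ~truth.emitter_on
        f1, f2 = dark[0].mean(), dark[1].mean()
        both = (dark[0] & dark[1]).mean()
        assert 0.15 < f1 < 0.25 and 0.15 < f2 < 0.25
        assert both == pytest.approx(f1 * f2, abs=0.012)
        assert both == pytest.approx(0.04, abs=0.02)

    def test_ground_truth_blink_mean_matches_renewal_rate(self):
        # interior all-dark run count over many seeds matches the entry rate
        # corrected for time spent dark, within 3 standard errors
        rate, dur, mean_dark = 0.18, 60.0, 3.0
        counts = [
            kb.simulate_kymograph(
                KymoSimParams(
                    photons_per_frame=0.0, background_sd=0.0, seed=s,
                    blink_rate_per_s=rate, mean_dark_frames=mean_dark,
                )
            )[1].true_blink_count
            for s in range(300)
        ]
        counts = np.array(counts)
        p_enter = 1.0 - np.exp(-rate * 0.1)
        # ON dwell mean (1-p)/p frames, dark dwell mean 3 frames
        cycles = 600.0 / ((1.0 - p_enter) / p_enter + mean_dark)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - cycles) <= 3 * se + 1.0  # boundary censoring ~<=1

    def test_tiff_roundtrip(self, tmp_path, default_kymo):
        kymo, truth = default_kymo
        simulate.write_kymograph_tiff(tmp_path / "k.tiff", kymo, truth)
        back, truth2 = simulate.read_kymograph_tiff(tmp_path / "k.tiff")
        np.testing.assert_allclose(back.intensity, kymo.intensity, rtol=1e-6)
        assert back.pixel_nm == kymo.pixel_nm
        assert truth2.true_blink_count == truth.true_blink_count


class TestSimulateBlinkCounts:
    def test_monomer_mean_obeys_law_of_large_numbers(self):
        p = MixtureSimParams(bl_mon=10.8, alpha=1.0, n_kymographs=100_000, seed=2)
        counts = kb.simulate_blink_counts(p)
        se = np.sqrt(10.8 / counts.size)
        assert abs(counts.mean() - 10.8) < 3 * se

    def test_dimer_mean_is_squared_rate_expectation(self):
        p = MixtureSimParams(bl_mon=10.8, duration_s=60.0, alpha=0.0,
                             n_kymographs=100_000, seed=3)
        counts = kb.simulate_blink_counts(p)
        se = np.sqrt(1.944 / counts.size)
        assert abs(counts.mean() - 1.944) < 3 * se

    def test_zero_rate_gives_all_zero_counts(self):
        p = MixtureSimParams(bl_mon=0.0, alpha=0.5, n_kymographs=1000, seed=4)
        assert not kb.simulate_blink_counts(p).any()

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_pure_components_pass_poisson_goodness_of_fit(self, alpha):
        p = MixtureSimParams(bl_mon=10.8, duration_s=60.0, alpha=alpha,
                             n_kymographs=10_000, seed=5)
        counts = kb.simulate_blink_counts(p)
        lam = 10.8 if alpha == 1.0 else kb.dimer_expected(10.8, 60.0)
        hi = max(int(counts.max()), 1)
        obs = np.bincount(counts, minlength=hi + 1).astype(float)
        exp = stats.poisson.pmf(np.arange(hi + 1), lam) * counts.size
        exp[-1] += (1.0 - stats.poisson.cdf(hi, lam)) * counts.size
        # merge sparse edge bins (expected < 5) inward
        obs, exp = list(obs), list(exp)
        while len(exp) > 2 and exp[-1] < 5:
            exp[-2] += exp.pop()
            obs[-2] += obs.pop()
        while len(exp) > 2 and exp[0] < 5:
            exp[1] += exp.pop(0)
            obs[1] += obs.pop(0)
        chi2, pval = stats.chisquare(obs, np.array(exp) * sum(obs) / sum(exp))
        assert pval > 0.01

    def test_reproducible_under_seed(self):
        p = MixtureSimParams(seed=9)
        np.testing.assert_array_equal(
            kb.simulate_blink_counts(p), kb.simulate_blink_counts(p)
        )


class TestSimulateDualColor:
    def test_all_dimers_half_dual_colored(self):
        obs = kb.simulate_dual_color_population(200_000, 1.0, seed=1)
        assert obs.n_dual / obs.n_total == pytest.approx(0.5, abs=0.01)

    def test_no_dimers_no_dual(self):
        obs = kb.simulate_dual_color_population(10_000, 0.0, seed=2)
        assert obs.n_dual == 0

    def test_thirty_percent_dimers_fifteen_percent_dual(self):
        obs = kb.simulate_dual_color_population(200_000, 0.30, seed=3)
        assert obs.n_dual / obs.n_total == pytest.approx(0.15, abs=0.01)

    def test_frequencies_converge_to_analytic_distribution(self):
        obs = kb.simulate_dual_color_population(
            100_000, 0.3, color_probs=(0.7, 0.3), seed=4, label_efficiency=0.9
        )
        exp = kb.expected_color_distribution(0.3, (0.7, 0.3), 0.9)
        emp = {
            "dual": obs.n_dual / obs.n_total,
            "single_a": obs.n_color_a / obs.n_total,
            "single_b": obs.n_color_b / obs.n_total,
        }
        tv = 0.5 * sum(abs(emp[k] - exp[k]) for k in emp)
        assert tv < 0.01

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            kb.simulate_dual_color_population(10, 1.5, seed=0)
        with pytest.raises(ValueError):
            kb.simulate_dual_color_population(10, 0.5, color_probs=(0.7, 0.7), seed=0)


class TestSimulateSpectra:
    def test_zero_coupling_zero_noise_mixture_equals_sum(self):
        a, b, mix = kb.simulate_spectra(0.0, "fret_excitation", seed=0, noise_sd=0.0)
        diff = kb.difference_spectrum(kb.sum_spectra([a, b]), mix)
        np.testing.assert_allclose(diff.signal, 0.0, atol=1e-12)

    def test_coupling_scales_deviation_linearly(self):
        a1, b1, m1 = kb.simulate_spectra(0.25, "fret_excitation", seed=0, noise_sd=0.0)
        a2, b2, m2 = kb.simulate_spectra(0.5, "fret_excitation", seed=0, noise_sd=0.0)
        d1 = kb.difference_spectrum(kb.sum_spectra([a1, b1]), m1)
        d2 = kb.difference_spectrum(kb.sum_spectra([a2, b2]), m2)
        np.testing.assert_allclose(d2.signal, 2.0 * d1.signal, atol=1e-12)

    def test_positive_coupling_enhances_donor_band(self):
        a, b, mix = kb.simulate_spectra(0.5, "fret_excitation", seed=1)
        diff = kb.difference_spectrum(kb.sum_spectra([a, b]), mix)
        score = kb.band_enhancement(diff, simulate.FRET_DONOR_BAND_NM)
        assert score.z_score > 0

    def test_determinism_and_kind_validation(self):
        s1 = kb.simulate_spectra(0.3, "cd", seed=8)
        s2 = kb.simulate_spectra(0.3, "cd", seed=8)
        for x, y in zip(s1, s2):
            np.testing.assert_array_equal(x.signal, y.signal)
        with pytest.raises(ValueError):
            kb.simulate_spectra(0.3, "absorbance", seed=0)
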