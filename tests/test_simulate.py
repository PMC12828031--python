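"""Synthetic TCSPC decays, cascade ensembles and tension scenes."""

import numpy as np
import pytest
from scipy import integrate

from cascadeflim import (
    ForceCalibration,
    KineticsSpec,
    fit_decay,
    lifetime_from_force,
    simulate_cascade_ensemble,
    simulate_decay,
    simulate_tension_scene,
    table_mixture,
)
from cascadeflim.errors import ConfigurationError, InvalidParameterError
from cascadeflim.simulate import VINCTS_FORCE_BIMODAL, make_adhesion_mask


class TestKineticsSpec:
    def test_fraction_sum_enforced(self):
        with pytest.raises(InvalidParameterError):
            KineticsSpec(components=((0.5, 1.0), (0.6, 4.0)))

    def test_positive_lifetimes(self):
        with pytest.raises(InvalidParameterError):
            KineticsSpec(components=((1.0, -2.0),))

    def test_min_bins(self):
        with pytest.raises(InvalidParameterError):
            KineticsSpec.mono(4.0, n_bins=8)

    def test_fractions_sum_to_one_over_period(self):
        spec = KineticsSpec(components=((0.4, 0.8), (0.6, 5.0)))
        assert spec.expected_fractions().sum() == pytest.approx(1.0, abs=1e-12)


def _wrapped_bin_expectation(tau, t0, t1, period, n_pulses=200):
    """Independent oracle: photon mass in [t0, t1] summed numerically over
    preceding pulses (no geometric closed form)."""
    total = 0.0
    for k in range(n_pulses):
        val, _ = integrate.quad(lambda t: np.exp(-(t + k * period) / tau), t0, t1)
        total += val / tau
    return total


class TestSimulateDecay:
    def test_zero_photons_zero_background(self):
        spec = KineticsSpec.mono(4.178)
        hist = simulate_decay(spec, 0, seed=0)
        assert hist.counts.sum() == 0

    def test_mono_exponential_lifetime_recovered(self):
        # intrinsic donor lifetime of the cascade donor
        spec = KineticsSpec.mono(4.178)
        hist = simulate_decay(spec, 1e6, seed=42)
        fit = fit_decay(hist)
        assert fit.converged
        assert fit.tau_intensity_weighted == pytest.approx(4.178, rel=0.01)

    def test_mono_exponential_mean_arrival_oracle(self):
        # closed-form mean arrival time of the wrapped exponential on [0, T):
        # E[t] = tau - T exp(-T/tau) / (1 - exp(-T/tau))
        tau, T = 4.178, 12.5
        spec = KineticsSpec.mono(tau, repetition_period_ns=T)
        hist = simulate_decay(spec, 1e6, seed=7)
        mean_t = float((hist.bin_centers * hist.counts).sum() / hist.counts.sum())
        expected = tau - T * np.exp(-T / tau) / (1 - np.exp(-T / tau))
        assert mean_t == pytest.approx(expected, rel=3e-3)

    def test_expectation_matches_numerical_integration(self):
        spec = KineticsSpec(components=((0.5, 1.0), (0.5, 4.0)))
        hist = simulate_decay(spec, 1.0, seed=0, expectation=True)
        edges = hist.edges_ns
        # photon weights of pre-exponential fractions (0.5, 0.5)
        w1 = 0.5 * 1.0 / (0.5 * 1.0 + 0.5 * 4.0)
        for k in [0, 1, 37, 128, 255]:
            expected = w1 * _wrapped_bin_expectation(1.0, edges[k], edges[k + 1], 12.5) + (
                1 - w1
            ) * _wrapped_bin_expectation(4.0, edges[k], edges[k + 1], 12.5)
            assert hist.counts[k] == pytest.approx(expected, rel=1e-10)

    def test_wraparound_mass_conservation(self):
        # expected mass equals the photon budget whatever tau/period is
        for tau in (0.3, 4.178, 11.0, 40.0):
            spec = KineticsSpec.mono(tau)
            hist = simulate_decay(spec, 5e5, seed=0, expectation=True)
            assert hist.counts.sum() == pytest.approx(5e5, rel=1e-12)

    def test_poisson_total_counts(self):
        spec = KineticsSpec.mono(2.5, background_rate=0.5)
        totals = [simulate_decay(spec, 2000, seed=s).counts.sum() for s in range(200)]
        expected = 2000 + 0.5 * spec.n_bins
        se = np.sqrt(expected / 200)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_determinism(self):
        spec = KineticsSpec.mono(4.178, background_rate=1.0)
        a = simulate_decay(spec, 1e5, seed=99)
        b = simulate_decay(spec, 1e5, seed=99)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_irf_preserves_mass_and_delays_peak(self):
        sharp = KineticsSpec.mono(2.0)
        blurred = KineticsSpec.mono(2.0, irf_sigma_ns=0.3)
        h0 = simulate_decay(sharp, 1e6, seed=0, expectation=True)
        h1 = simulate_decay(blurred, 1e6, seed=0, expectation=True)
        assert h1.counts.sum() == pytest.approx(h0.counts.sum(), rel=1e-9)
        assert np.argmax(h1.counts) >= np.argmax(h0.counts)

    def test_invalid_photons(self):
        with pytest.raises(InvalidParameterError):
            simulate_decay(KineticsSpec.mono(4.0), -1, seed=0)


class TestCascadeEnsemble:
    def test_forster_radius_distance_halves_lifetime(self, three_colour_pairs):
        # every separation at its R0: each pairwise construct has E = 0.5
        dist = {k: p.R0_nm for k, p in three_colour_pairs.items()}
        ens = simulate_cascade_ensemble(three_colour_pairs, dist, seed=0, expectation=True)
        tau = fit_decay(ens["mTurq2-mVenus"]).tau_intensity_weighted
        assert tau == pytest.approx(4.178 / 2, rel=1e-6)

    def test_three_colour_equals_rate_sum(self, three_colour_pairs):
        dist = {
            ("mTurq2", "mVenus"): 6.41,
            ("mTurq2", "mScarlet"): 6.25,
            ("mVenus", "mScarlet"): 7.21,
        }
        ens = simulate_cascade_ensemble(three_colour_pairs, dist, seed=0, expectation=True)
        g1 = (1 / 4.178) * (5.83 / 6.41) ** 6
        g2 = (1 / 4.178) * (5.08 / 6.25) ** 6
        expected = 1.0 / (1 / 4.178 + g1 + g2)
        tau = fit_decay(ens["mTurq2-mVenus-mScarlet"]).tau_intensity_weighted
        assert tau == pytest.approx(expected, rel=1e-6)

    def test_back_solved_distances_reproduce_lifetimes(self, three_colour_pairs):
        # distances solved from the printed construct lifetimes; the simulated
        # decays must fit back to those lifetimes at 1e6 photons
        from cascadeflim import separation_from_rate, transfer_rate

        dist = {
            ("mTurq2", "mVenus"): separation_from_rate(
                transfer_rate(2.668, 4.178), 4.178, 5.83
            ),
            ("mTurq2", "mScarlet"): separation_from_rate(
                transfer_rate(3.242, 4.178), 4.178, 5.08
            ),
            ("mVenus", "mScarlet"): separation_from_rate(
                transfer_rate(2.509, 3.020), 3.020, 5.53
            ),
        }
        ens = simulate_cascade_ensemble(three_colour_pairs, dist, seed=5, total_photons=1e6)
        expected = {
            "mTurq2": 4.178,
            "mTurq2-mVenus": 2.668,
            "mTurq2-dark(mVenus)-mScarlet": 3.242,
            "mVenus-mScarlet": 2.509,
        }
        for name, tau in expected.items():
            fit = fit_decay(ens[name])
            assert fit.tau_intensity_weighted == pytest.approx(tau, rel=0.01), name

    def test_missing_pair_parameters(self, three_colour_pairs):
        with pytest.raises(ConfigurationError):
            simulate_cascade_ensemble(
                three_colour_pairs, {("mTurq2", "unknown"): 5.0}, seed=0
            )


class TestTensionScene:
    def test_degenerate_mixture_uniform_force(self, ts_pair, ts_calibration):
        scene, _ = simulate_tension_scene(
            pop1=(3.0, 0.0, 0.5), pop2=(3.0, 0.0, 0.5),
            pair=ts_pair, calibration=ts_calibration,
            image_shape=(24, 24), photons_per_pixel=100, seed=0,
        )
        inside = scene.adhesion_mask
        assert inside.sum() > 0
        np.testing.assert_allclose(scene.force_truth_pN[inside], 3.0)

    def test_mixture_mean_matches_analytic(self, ts_pair, ts_calibration):
        pop1, pop2 = table_mixture(**VINCTS_FORCE_BIMODAL)
        mask = np.ones((100, 100), dtype=bool)
        scene, _ = simulate_tension_scene(
            pop1, pop2, ts_pair, ts_calibration,
            image_shape=(100, 100), photons_per_pixel=0, seed=3, mask=mask,
            cytoplasm_photon_frac=0.0,
        )
        v = scene.force_truth_pN[mask]
        analytic = pop1[2] * pop1[0] + pop2[2] * pop2[0]
        mix_var = (
            pop1[2] * (pop1[1] ** 2 + pop1[0] ** 2)
            + pop2[2] * (pop2[1] ** 2 + pop2[0] ** 2)
            - analytic**2
        )
        se = np.sqrt(mix_var / v.size)
        assert abs(v.mean() - analytic) < 3 * se

    def test_scene_determinism_bit_identical(self, ts_pair, ts_calibration):
        kwargs = dict(
            pop1=(2.7, 0.3, 0.6), pop2=(3.2, 0.2, 0.4),
            pair=ts_pair, calibration=ts_calibration,
            image_shape=(16, 16), photons_per_pixel=500, seed=11,
        )
        s1, st1 = simulate_tension_scene(**kwargs)
        s2, st2 = simulate_tension_scene(**kwargs)
        np.testing.assert_array_equal(st1, st2)
        np.testing.assert_array_equal(s1.force_truth_pN, s2.force_truth_pN)

    def test_pixel_streams_independent_of_image_size(self, ts_pair, ts_calibration):
        mask_small = np.zeros((8, 8), dtype=bool)
        mask_small[2, 3] = True
        mask_big = np.zeros((16, 16), dtype=bool)
        mask_big[2, 3] = True
        kwargs = dict(
            pop1=(2.7, 0.3, 0.6), pop2=(3.2, 0.2, 0.4),
            pair=ts_pair, calibration=ts_calibration,
            photons_per_pixel=500, seed=11, cytoplasm_photon_frac=0.0,
        )
        s1, st1 = simulate_tension_scene(image_shape=(8, 8), mask=mask_small, **kwargs)
        s2, st2 = simulate_tension_scene(image_shape=(16, 16), mask=mask_big, **kwargs)
        np.testing.assert_array_equal(st1[:, 2, 3], st2[:, 2, 3])

    def test_invalid_force_names_pixel(self, ts_pair):
        # an absurd force drives the implied efficiency to the edge of (0, 1)
        cal = ForceCalibration(linker_n=40, r_TL_nm=4.2)
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(InvalidParameterError, match=r"pixel \(0, 0\)"):
            simulate_tension_scene(
                pop1=(1e60, 0.0, 0.5), pop2=(1e60, 0.0, 0.5),
                pair=ts_pair, calibration=cal,
                image_shape=(2, 2), photons_per_pixel=10, seed=0, mask=mask,
            )

    def test_lifetime_truth_matches_forward_model(self, ts_pair, ts_calibration):
        scene, _ = simulate_tension_scene(
            pop1=(3.0, 0.0, 0.5), pop2=(3.0, 0.0, 0.5),
            pair=ts_pair, calibration=ts_calibration,
            image_shape=(16, 16), photons_per_pixel=10, seed=2,
        )
        expected = lifetime_from_force(3.0, ts_pair, ts_calibration)
        inside = scene.adhesion_mask
        np.testing.assert_allclose(scene.lifetime_truth_ns[inside], expected)


def test_adhesion_mask_is_peripheral_and_reproducible():
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    m1 = make_adhesion_mask((48, 48), rng1)
    m2 = make_adhesion_mask((48, 48), rng2)
    np.testing.assert_array_equal(m1, m2)
    assert 0 < m1.sum() < m1.size
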