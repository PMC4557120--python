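"""Variable-projection global lifetime fitting and the EMG basis."""

import warnings

import numpy as np
import pytest
from scipy.optimize import least_squares

from photokin import (
    ExponentialBasis,
    SpectroTemporalMatrix,
    ValidationError,
    build_basis,
    exp_conv_gauss,
    fit_global,
    long_lived_constant_check,
    solve_linear_amplitudes,
    synth,
)

PS = 1e-12


def _data(values, times, wavelengths=None):
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float) + 400.0
    return SpectroTemporalMatrix(values, times, wavelengths, window="fs_ns")


class TestBasis:
    def test_pure_exponential_without_irf(self):
        basis = ExponentialBasis([1.0], t0=0.0, irf_fwhm=0.0)
        t = np.linspace(-1.0, 5.0, 200)
        F = build_basis(basis, t)
        expected = np.where(t >= 0, np.exp(-np.clip(t, 0, None)), 0.0)
        np.testing.assert_allclose(F[:, 0], expected, atol=1e-14)

    def test_convolved_column_reaches_asymptotic_exponential(self):
        # far past the pulse the EMG is a pure exponential
        fwhm = 170e-15
        t = np.linspace(5 * fwhm, 20 * PS, 50)
        emg = exp_conv_gauss(t, 5 * PS, 0.0, fwhm)
        sigma = fwhm / 2.3548200450309493
        analytic = np.exp(sigma**2 / (2 * (5 * PS) ** 2) - t / (5 * PS))
        np.testing.assert_allclose(emg, analytic, rtol=1e-6)

    def test_emg_matches_brute_force_convolution(self):
        # trapezoidal convolution of a causal exponential with the
        # normalized Gaussian IRF on a fine symmetric grid
        from scipy.signal import fftconvolve

        fwhm, tau, t0 = 0.35, 1.3, 0.2
        sigma = fwhm / 2.3548200450309493
        dt = 2e-5
        fine = -9.0 + dt * np.arange(900001)       # t0 lies on the grid
        decay = np.where(fine > t0, np.exp(-(fine - t0) / tau), 0.0)
        decay[460000] = 0.5                        # trapezoid at the jump
        gauss = np.exp(-0.5 * (fine / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        conv = fftconvolve(decay, gauss, mode="same") * dt
        probe = slice(400000, 800000, 10000)
        emg = exp_conv_gauss(fine[probe], tau, t0, fwhm)
        np.testing.assert_allclose(emg, conv[probe], atol=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValidationError):
            ExponentialBasis([1.0], irf_fwhm=-1.0)

    def test_unsorted_lifetimes_rejected(self):
        with pytest.raises(ValidationError):
            ExponentialBasis([2.0, 1.0])


class TestLinearAmplitudes:
    def test_exact_recovery_of_noise_free_amplitudes(self, rng):
        t = np.geomspace(0.1, 50.0, 60)
        basis = ExponentialBasis([1.0, 10.0], has_constant=True)
        F = build_basis(basis, t)
        B_true = rng.normal(size=(3, 7))
        data = _data(F @ B_true, t)
        B, chi2 = solve_linear_amplitudes(data, F)
        np.testing.assert_allclose(B, B_true, atol=1e-10)
        assert chi2 < 1e-18

    def test_least_squares_optimality(self, rng):
        t = np.geomspace(0.1, 50.0, 40)
        F = build_basis(ExponentialBasis([1.0, 8.0]), t)
        data = _data(F @ rng.normal(size=(2, 5)) +
                     rng.normal(0, 0.01, (40, 5)), t)
        B, chi2 = solve_linear_amplitudes(data, F)
        for _ in range(50):
            pert = B + rng.normal(0, 0.01, B.shape)
            assert np.sum((data.values - F @ pert) ** 2) >= chi2

    def test_near_degenerate_lifetimes_warn(self):
        t = np.geomspace(0.1, 50.0, 40)
        F = build_basis(ExponentialBasis([1.0, 1.01]), t)
        data = _data(np.ones((40, 3)), t)
        with pytest.warns(UserWarning, match="near-degenerate"):
            solve_linear_amplitudes(data, F)


class TestFitGlobal:
    def test_single_noise_free_exponential_exact(self):
        t = np.geomspace(1 * PS, 2000 * PS, 80)
        tau = 100 * PS
        F = build_basis(ExponentialBasis([tau]), t)
        data = _data(np.outer(F[:, 0], [1.0, -0.5, 0.2]), t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_global(data, ExponentialBasis([30 * PS]), n_starts=3)
        assert res.lifetimes[0] == pytest.approx(tau, rel=1e-6)

    def test_matches_brute_force_grid_search(self, rng):
        t = np.geomspace(1 * PS, 3000 * PS, 60)
        tau = 170 * PS
        F = build_basis(ExponentialBasis([tau]), t)
        data = _data(np.outer(F[:, 0], rng.normal(size=4)) +
                     rng.normal(0, 0.01, (60, 4)), t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_global(data, ExponentialBasis([50 * PS]), n_starts=3)
        grid = np.geomspace(10 * PS, 1000 * PS, 1000)
        chi2s = []
        for tg in grid:
            Fg = build_basis(ExponentialBasis([tg]), t)
            _, c = solve_linear_amplitudes(data, Fg)
            chi2s.append(c)
        best = grid[int(np.argmin(chi2s))]
        assert res.lifetimes[0] == pytest.approx(best, rel=0.01)

    def test_variable_projection_equals_joint_fit(self, rng):
        # 10x8 instance: joint nonlinear fit over (tau, B) lands at the
        # same chi2 as variable projection within 1e-8
        t = np.geomspace(0.05, 20.0, 10)
        tau_true = 2.0
        F = build_basis(ExponentialBasis([tau_true]), t)
        data = _data(np.outer(F[:, 0], rng.normal(size=8)) +
                     rng.normal(0, 0.02, (10, 8)), t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_global(data, ExponentialBasis([1.0]), n_starts=3)

        def joint_resid(p):
            Fj = build_basis(ExponentialBasis([np.exp(p[0])]), t)
            return (data.values - np.outer(Fj[:, 0], p[1:])).ravel()

        sol = least_squares(joint_resid, np.concatenate([[0.0],
                                                         data.values[0]]),
                            xtol=1e-15, ftol=1e-15)
        chi2_joint = float(np.sum(sol.fun ** 2))
        assert res.chi2 == pytest.approx(chi2_joint, abs=1e-8)

    def test_chi2_invariant_under_wavelength_permutation(self, rng):
        m, _ = synth.generate_transient(
            synth.SyntheticSpec(seed=5, noise_rms=0.005), "ns_us")
        perm = rng.permutation(m.n_wavelengths)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = fit_global(m, ExponentialBasis([0.3e-6], has_constant=True),
                            n_starts=2)
            m2 = SpectroTemporalMatrix(
                m.values[:, perm], m.time_axis,
                np.sort(m.wavelength_axis[perm]), window=m.window)
            r2 = fit_global(m2, ExponentialBasis([0.3e-6],
                                                 has_constant=True),
                            n_starts=2)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)

    def test_deterministic_given_identical_inputs(self):
        m, _ = synth.generate_transient(
            synth.SyntheticSpec(seed=2, noise_rms=0.005), "ns_us")
        init = ExponentialBasis([0.2e-6], has_constant=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = fit_global(m, init, n_starts=2)
            r2 = fit_global(m, init, n_starts=2)
        assert r1.lifetimes[0] == r2.lifetimes[0]
        assert r1.chi2 == r2.chi2


class TestLongLivedCheck:
    def _fit_fs(self, include_offset):
        spec = synth.SyntheticSpec(seed=6, noise_rms=0.005,
                                   include_pre_t0_offset=include_offset)
        m, truth = synth.generate_transient(spec, "fs_ns")
        init = ExponentialBasis([1 * PS, 300 * PS], has_constant=True,
                                has_offset=True, irf_fwhm=170e-15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dads = fit_global(m, init)
        pre = m.values[m.time_axis < -5 * 170e-15].mean(axis=0)
        return dads, pre

    def test_injected_long_lived_species_flagged(self):
        dads, pre = self._fit_fs(True)
        report = long_lived_constant_check(dads, pre)
        assert report["long_lived"] is True
        assert report["correlation"] > 0.9

    def test_absent_long_lived_species_not_flagged(self):
        dads, pre = self._fit_fs(False)
        report = long_lived_constant_check(dads, pre)
        assert report["long_lived"] is False
        assert abs(report["correlation"] or 0.0) < 0.3

    def test_zero_constant_spectrum_not_applicable(self):
        dads, pre = self._fit_fs(True)
        dads.B[dads.basis.column_names().index("offset")] = 0.0
        report = long_lived_constant_check(dads, pre)
        assert report["correlation"] is None

    def test_missing_pre_t0_rows_rejected(self):
        dads, _ = self._fit_fs(True)
        with pytest.raises(ValidationError):
            long_lived_constant_check(dads, np.array([]))
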