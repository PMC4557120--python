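"""Kinetic schemes, analytic concentrations, model-matrix projection, SAS."""

import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from photokin import (
    ExponentialBasis,
    KineticScheme,
    ValidationError,
    branching_ratios,
    build_basis,
    fit_global,
    infer_branching,
    project_to_sas,
    scheme_concentrations,
    scheme_to_model_matrix,
    synth,
    validate_model,
)
from photokin.svd import ModelMatrix

PS = 1e-12
K1 = synth.K1


class TestSchemeValidation:
    def test_cycles_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            KineticScheme(["A", "B"], [("A", "B", 1.0), ("B", "A", 1.0)], "A")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError, match="> 0"):
            KineticScheme(["A", "B"], [("A", "B", 0.0)], "A")

    def test_rate_matrix_columns_sum_to_zero(self):
        K = synth.full_photocycle().rate_matrix()
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-3)


class TestBranchingRatios:
    def test_printed_microscopic_rates(self):
        # k_D, k_HomoC, k_CT -> alpha = 0.894, beta = 0.022, gamma = 0.084
        r = branching_ratios(synth.full_photocycle(), "A")
        assert r["GS"] == pytest.approx(0.894, abs=5e-4)
        assert r["B"] == pytest.approx(0.022, abs=1e-3)
        assert r["C"] == pytest.approx(0.084, abs=1e-3)
        assert sum(r.values()) == 1.0

    def test_total_entry_rate_is_inverse_printed_lifetime(self):
        # 1/(k_D + k_HomoC + k_CT) = 1.9 ps
        assert 1.0 / K1 == pytest.approx(1.9e-12, rel=0.005)

    def test_single_edge_ratio_one(self):
        s = KineticScheme(["A", "B"], [("A", "B", 7.0)], "A")
        assert branching_ratios(s, "A") == {"B": 1.0}

    def test_equal_rates_split_evenly(self):
        s = KineticScheme(["A", "B", "C"],
                          [("A", "B", 2.0), ("A", "C", 2.0)], "A")
        assert branching_ratios(s, "A") == {"B": 0.5, "C": 0.5}

    def test_sink_has_no_ratios(self):
        s = KineticScheme(["A", "B"], [("A", "B", 1.0)], "A")
        with pytest.raises(ValidationError):
            branching_ratios(s, "B")


class TestSchemeConcentrations:
    def test_entry_population_at_time_zero(self):
        c = scheme_concentrations(synth.full_photocycle(), [0.0])
        scheme = synth.full_photocycle()
        np.testing.assert_allclose(
            c[0], [1.0 if s == "A" else 0.0 for s in scheme.species],
            atol=1e-12)

    def test_two_step_peak_time(self):
        # A -> B -> GS with k1 = 0.527e12/s, k2 = 1.26e9/s:
        # B(t) peaks at ln(k1/k2)/(k1 - k2) ~ 11.5 ps
        k2 = synth.RATES["k_RPR"]
        s = KineticScheme(["A", "B", "GS"],
                          [("A", "B", K1), ("B", "GS", k2)], "A",
                          ground_state="GS")
        t = np.linspace(0.0, 60e-12, 6001)
        c = scheme_concentrations(s, t)
        t_peak = t[int(np.argmax(c[:, 1]))]
        expected = np.log(K1 / k2) / (K1 - k2)
        assert expected == pytest.approx(11.5e-12, abs=0.1e-12)
        assert t_peak == pytest.approx(expected, rel=0.01)

    def test_population_conserved_at_random_times(self, rng):
        t = np.sort(rng.uniform(0.0, 1e-9, 50))
        c = scheme_concentrations(synth.full_photocycle(), t)
        np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_ode_integrator_on_random_schemes(self, rng):
        for trial in range(10):
            n = int(rng.integers(2, 7))
            labels = [f"S{i}" for i in range(n)]
            edges = []
            for i in range(n - 1):
                targets = rng.choice(np.arange(i + 1, n),
                                     size=min(int(rng.integers(1, 3)),
                                              n - 1 - i), replace=False)
                for j in targets:
                    edges.append((labels[i], labels[int(j)],
                                  float(rng.uniform(0.5, 20.0))))
            scheme = KineticScheme(labels, edges, labels[0])
            K = scheme.rate_matrix()
            t = np.linspace(0.0, 2.0, 40)
            c0 = np.zeros(n)
            c0[0] = 1.0
            sol = solve_ivp(lambda _, y: K @ y, (0.0, 2.0), c0, t_eval=t,
                            rtol=1e-11, atol=1e-13)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = scheme_concentrations(scheme, t)
            np.testing.assert_allclose(c, sol.y.T, atol=1e-8)

    def test_degenerate_rates_perturbed_with_warning(self):
        s = KineticScheme(["A", "B", "C"],
                          [("A", "B", 1.0), ("B", "C", 1.0)], "A")
        with pytest.warns(UserWarning, match="degenerate"):
            c = scheme_concentrations(s, np.linspace(0, 3, 10))
        np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-6)


class TestModelMatrix:
    def test_single_species_decay_is_identity(self):
        s = KineticScheme(["A", "GS"], [("A", "GS", 2.0)], "A",
                          ground_state="GS")
        basis = ExponentialBasis([0.5])
        X = scheme_to_model_matrix(s, basis)
        np.testing.assert_allclose(X.X, [[1.0]], atol=1e-12)

    def test_sequential_two_compartment_closed_form(self):
        # A -> B -> GS, k1 >> k2: B carries (-c, +c) on (e^-k1t, e^-k2t)
        # with c = k1/(k1 - k2) from the closed two-compartment solution
        k1, k2 = 50.0, 2.0
        s = KineticScheme(["GS", "A", "B"],
                          [("A", "B", k1), ("B", "GS", k2)], "A",
                          ground_state="GS")
        X = scheme_to_model_matrix(s, ExponentialBasis([1 / k1, 1 / k2]))
        c = k1 / (k1 - k2)
        row_b = X.X[s.observed_species.index("B")]
        np.testing.assert_allclose(row_b, [-c, c], rtol=1e-10)

    def test_f_xt_reproduces_scheme_concentrations(self):
        scheme = synth.fs_ns_scheme()
        basis = ExponentialBasis([1.0 / K1, 1.0 / synth.RATES["k_RPR"]],
                                 has_constant=True)
        X = scheme_to_model_matrix(scheme, basis)
        t = np.geomspace(1e-14, 3e-9, 100)
        F = build_basis(basis, t)[:, :basis.n_kinetic]
        C = F @ X.X.T
        rows = [scheme.species.index(s) for s in scheme.observed_species]
        np.testing.assert_allclose(C, scheme_concentrations(scheme, t)[:, rows],
                                   atol=1e-8)

    def test_rate_mismatch_rejected(self):
        scheme = synth.fs_ns_scheme()
        basis = ExponentialBasis([5e-12, 5e-10], has_constant=True)
        with pytest.raises(ValidationError, match="mismatch"):
            scheme_to_model_matrix(scheme, basis)

    def test_species_count_mismatch_rejected(self):
        scheme = synth.fs_ns_scheme()
        basis = ExponentialBasis([1.0 / K1])
        with pytest.raises(ValidationError, match="partition"):
            scheme_to_model_matrix(scheme, basis)


class TestProjection:
    def _fs_fit(self, seed=7):
        m, truth = synth.generate_transient(
            synth.SyntheticSpec(seed=seed, noise_rms=0.005), "fs_ns")
        init = ExponentialBasis([1 * PS, 300 * PS], has_constant=True,
                                has_offset=True, irf_fwhm=170e-15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dads = fit_global(m, init)
        return m, truth, dads

    def test_identity_model_matrix_returns_dads(self):
        _, truth, dads = self._fs_fit()
        nk = dads.basis.n_kinetic
        sas = project_to_sas(dads, ModelMatrix(np.eye(nk)),
                             truth["gs_spectrum"], 0.1)
        np.testing.assert_allclose(sas.difference_spectra, dads.B[:nk],
                                   atol=1e-12)

    def test_chi2_bit_identical_for_random_rotations(self, rng):
        _, truth, dads = self._fs_fit()
        nk = dads.basis.n_kinetic
        for _ in range(10):
            X = rng.normal(size=(nk, nk)) + 3 * np.eye(nk)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sas = project_to_sas(dads, ModelMatrix(X),
                                     truth["gs_spectrum"], 0.1)
            assert sas.chi2 == dads.chi2  # bitwise

    def test_recovered_sas_match_generator_spectra(self):
        _, truth, dads = self._fs_fit()
        scheme = truth["scheme"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X = scheme_to_model_matrix(scheme, dads.basis, rate_tol=0.15)
            sas = project_to_sas(dads, X, truth["gs_spectrum"],
                                 truth["excited_fraction"],
                                 species=scheme.observed_species)
        for i, label in enumerate(scheme.observed_species):
            true_spec = truth["species_spectra"][i]
            err = np.sqrt(np.mean((sas.species_spectra[i] - true_spec) ** 2))
            # minor-branch SAS noise is amplified by the inverse branch
            # fraction (1/beta ~ 45x for B, 1/gamma ~ 12x for C); the
            # dominant excited state recovers tightly
            tol = {"A": 0.02, "B": 0.10, "C": 0.05}[label]
            assert err < tol * np.abs(truth["gs_spectrum"]).max(), label

    def test_bad_excited_fraction_rejected(self):
        _, truth, dads = self._fs_fit()
        nk = dads.basis.n_kinetic
        with pytest.raises(ValidationError):
            project_to_sas(dads, ModelMatrix(np.eye(nk)),
                           truth["gs_spectrum"], 0.0)


class TestBranchingRecovery:
    def test_end_to_end_branching_within_one_point(self):
        m, truth, dads = TestProjection()._fs_fit(seed=7)
        k1 = 1.0 / dads.lifetimes[0]
        k2 = 1.0 / dads.lifetimes[1]
        scheme = KineticScheme(
            ["GS", "A", "B", "C"],
            [("A", "GS", 0.9 * k1), ("A", "B", 0.05 * k1),
             ("A", "C", 0.05 * k1), ("B", "GS", k2)],
            "A", ground_state="GS")
        est = infer_branching(dads, scheme, truth["gs_spectrum"],
                              truth["excited_fraction"])
        for channel, val in truth["branching"].items():
            assert est[channel] == pytest.approx(val, abs=0.01), channel
        assert sum(est.values()) == pytest.approx(1.0, abs=1e-9)


class TestValidateModel:
    @staticmethod
    def _fitted_scheme(dads, alpha, beta, gamma):
        k1, k2 = 1.0 / dads.lifetimes[0], 1.0 / dads.lifetimes[1]
        return KineticScheme(
            ["GS", "A", "B", "C"],
            [("A", "GS", alpha * k1), ("A", "B", beta * k1),
             ("A", "C", gamma * k1), ("B", "GS", k2)],
            "A", ground_state="GS")

    def test_matching_scheme_passes_physicality(self):
        _, truth, dads = TestProjection()._fs_fit()
        good = self._fitted_scheme(dads, 0.894, 0.022, 0.084)
        report = validate_model([good], dads, truth["gs_spectrum"],
                                excited_fraction=truth["excited_fraction"])
        assert report[0]["rate_match"]
        assert report[0]["flags"] == []

    def test_under_allocated_branch_rates_flagged(self):
        _, truth, dads = TestProjection()._fs_fit()
        # a model granting the intermediates far less population than the
        # data contain inflates their difference spectra and drives the
        # absolute SAS negative where the ground state absorbs
        bad = self._fitted_scheme(dads, 0.975, 0.005, 0.02)
        good = self._fitted_scheme(dads, 0.894, 0.022, 0.084)
        report = validate_model([bad, good], dads, truth["gs_spectrum"],
                                excited_fraction=truth["excited_fraction"])
        by_index = {r["index"]: r for r in report}
        assert by_index[0]["sas_negativity"] > by_index[1]["sas_negativity"]
        assert by_index[1]["rank"] < by_index[0]["rank"]

    def test_empty_candidate_list_rejected(self):
        _, truth, dads = TestProjection()._fs_fit()
        with pytest.raises(ValidationError, match="empty"):
            validate_model([], dads, truth["gs_spectrum"])
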