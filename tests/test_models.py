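"""Correction models: power-law correction, joint constrained fit, baselines, oracle."""

import numpy as np
import pytest

import fluorocorr as fc
from fluorocorr.models import (
    FitOptions,
    ReflectanceCorrection,
    alpha_profile_oracle,
    calibrate_valdes_alpha,
    correct_power,
    fit_adaptive,
    fit_fixed_alpha,
    multistart_robustness,
)
from fluorocorr.simulate import make_suite_phantoms, simulate_fluorescence, simulate_reflectance
from fluorocorr.spectra import Spectrum


def two_basis_library(grid):
    """Two well-separated measured bases for exact-recovery checks."""
    from fluorocorr.basis import BasisLibrary, MeasuredBasis, gaussian_component

    fa = gaussian_component(grid, 500.0, 15.0)
    fb = gaussian_component(grid, 580.0, 15.0)
    return BasisLibrary(
        measured=[MeasuredBasis("A", 375, fa), MeasuredBasis("B", 375, fb)],
        gaussian=[], fit_range=(480.0, 620.0))


def structured_reflectance(grid):
    vals = 0.9 * np.exp(-0.8 * np.exp(-((grid - 550.0) ** 2) / (2 * 25.0 ** 2)))
    return Spectrum(grid, vals, "reflectance")


class TestCorrectPower:
    def test_alpha_zero_is_identity(self, grid):
        fm = Spectrum(grid, np.abs(np.sin(grid / 30.0)) + 0.1, "fluorescence")
        r = structured_reflectance(grid)
        np.testing.assert_array_equal(correct_power(fm, r, 0.0).values, fm.values)

    def test_unit_reflectance_is_identity_for_any_alpha(self, grid):
        fm = Spectrum(grid, np.full(grid.shape, 2.0), "fluorescence")
        r = Spectrum(grid, np.ones_like(grid), "reflectance")
        for alpha in (0.0, 0.3, 1.0):
            np.testing.assert_array_equal(correct_power(fm, r, alpha).values, fm.values)

    def test_square_root_correction_arithmetic(self):
        fm = Spectrum(np.array([500.0, 510.0]), np.array([1.0, 1.0]), "fluorescence")
        r = Spectrum(np.array([500.0, 510.0]), np.array([0.25, 1.0]), "reflectance")
        np.testing.assert_allclose(correct_power(fm, r, 0.5).values, [2.0, 1.0])

    def test_grid_mismatch_errors(self, grid):
        fm = Spectrum(grid, np.ones_like(grid), "fluorescence")
        r = Spectrum(grid + 1.0, np.ones_like(grid), "reflectance")
        with pytest.raises(ValueError):
            correct_power(fm, r, 0.5)


class TestFixedAlphaFit:
    def test_exact_linear_recovery_with_unit_reflectance(self, grid):
        lib = two_basis_library(grid)
        a = lib.design_matrix(grid)
        fm = Spectrum(grid, a @ np.array([0.7, 0.3]), "fluorescence")
        r = Spectrum(grid, np.ones_like(grid), "reflectance")
        res = fit_fixed_alpha(fm, r, 1.0, lib)
        assert res.fractions["A"] == pytest.approx(0.7, abs=1e-9)
        assert res.fractions["B"] == pytest.approx(0.3, abs=1e-9)
        assert res.mse < 1e-20

    def test_kim_correction_inverts_true_unit_alpha_distortion(self, grid):
        lib = two_basis_library(grid)
        a = lib.design_matrix(grid)
        r = structured_reflectance(grid)
        fm = Spectrum(grid, (a @ np.array([0.5, 0.5])) * r.values, "fluorescence")
        res = fit_fixed_alpha(fm, r, 1.0, lib)
        assert res.fractions["A"] == pytest.approx(0.5, abs=1e-6)
        assert res.mse < 1e-12
        # not correcting at all leaves a strictly worse residual
        res0 = fit_fixed_alpha(fm, r, 0.0, lib)
        assert res0.mse > res.mse + 1e-8

    def test_fractions_sum_to_one(self, grid):
        lib = two_basis_library(grid)
        a = lib.design_matrix(grid)
        fm = Spectrum(grid, a @ np.array([0.2, 0.8]) + 1e-3, "fluorescence")
        r = structured_reflectance(grid)
        res = fit_fixed_alpha(fm, r, 0.5, lib)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in res.amplitudes.values())


class TestAdaptiveFit:
    def test_noiseless_joint_recovery(self, noiseless_suite, phantom_library):
        for rec in noiseless_suite:
            res = fit_adaptive(rec.fluorescence, rec.reflectance, phantom_library)
            assert res.alpha == pytest.approx(rec.spec.true_alpha, abs=0.01)
            for name, truth in rec.truth_fractions.items():
                assert res.fractions[name] == pytest.approx(truth, abs=0.01)

    def test_constant_reflectance_flags_alpha_unidentifiable(self, grid):
        lib = two_basis_library(grid)
        a = lib.design_matrix(grid)
        fm = Spectrum(grid, a @ np.array([0.6, 0.4]), "fluorescence")
        r = Spectrum(grid, np.full(grid.shape, 0.8), "reflectance")
        res = fit_adaptive(fm, r, lib)
        assert not res.alpha_identifiable
        assert res.alpha == 0.0
        # fractions equal the plain uncorrected fit
        plain = fit_fixed_alpha(fm, r, 0.0, lib)
        for name in res.fractions:
            assert res.fractions[name] == pytest.approx(plain.fractions[name], abs=1e-9)

    def test_fixed_alpha_misassigns_an_absent_fluorophore(self, noisy_suite,
                                                          phantom_library):
        """On a NADH/TiO2 phantom with strong green absorption, the alpha=1
        correction overcorrects and invents a large FAD fraction; the adaptive
        fit keeps the absent fluorophore below the detection floor."""
        rec = [r for r in noisy_suite
               if r.excitation_tag == "375" and r.spec.id == "phantom_7"][0]
        model = ReflectanceCorrection(rec.fluorescence, rec.reflectance, phantom_library)
        adaptive = model.fit("adaptive")
        kim = model.fit("kim")
        assert adaptive.fractions["FAD"] < 0.01
        assert kim.fractions["FAD"] > 0.05

    def test_scale_invariance_of_alpha_and_fractions(self, noiseless_suite,
                                                     phantom_library):
        rec = noiseless_suite[3]
        res1 = fit_adaptive(rec.fluorescence, rec.reflectance, phantom_library)
        scaled = rec.fluorescence.copy(values=rec.fluorescence.values * 37.0)
        res2 = fit_adaptive(scaled, rec.reflectance, phantom_library)
        assert res2.alpha == pytest.approx(res1.alpha, abs=1e-6)
        for name in res1.fractions:
            assert res2.fractions[name] == pytest.approx(res1.fractions[name], abs=1e-9)

    def test_exact_inversion_of_the_forward_model(self, noiseless_suite,
                                                  phantom_library):
        """Recovered corrected spectrum equals the generating mixture."""
        rec = noiseless_suite[5]
        res = fit_adaptive(rec.fluorescence, rec.reflectance, phantom_library)
        rel = np.abs(res.corrected.values - res.model.values).max() / res.model.values.max()
        assert rel < 1e-6

    def test_optimality_dominance_over_fixed_alpha(self, noisy_suite, phantom_library):
        for rec in noisy_suite[:6]:
            model = ReflectanceCorrection(rec.fluorescence, rec.reflectance,
                                          phantom_library)
            adaptive = model.fit("adaptive").mse
            assert adaptive <= model.fit("none").mse + 1e-8
            assert adaptive <= model.fit("kim").mse + 1e-8
            assert adaptive <= model.fit("valdes", alpha=0.6).mse + 1e-8

    def test_gaussian_fit_stays_inside_constraint_boxes(self, liver_library):
        pts = fc.generate_timecourse()
        p = pts[0]
        res = fc.ReflectanceCorrection(p.fluorescence, p.reflectance, liver_library,
                                       FitOptions(n_starts=2)).fit("adaptive")
        for g in liver_library.gaussian:
            mu, sigma = res.gaussian_fit[g.name]
            assert g.contains(mu, sigma)

    def test_summary_lists_components_and_alpha(self, noiseless_suite, phantom_library):
        rec = noiseless_suite[0]
        res = fit_adaptive(rec.fluorescence, rec.reflectance, phantom_library)
        text = res.summary()
        for name in phantom_library.component_names:
            assert name in text
        assert "alpha" in text


class TestValdesCalibration:
    def test_shared_alpha_recovered_from_suite(self, grid, phantom_library):
        phantoms = make_suite_phantoms(0, noise_cv=0.0)
        for ph in phantoms:
            ph.true_alpha = 0.55
        pairs = [(simulate_fluorescence(ph, phantom_library, grid, "375"),
                  simulate_reflectance(ph, grid)) for ph in phantoms]
        cal = calibrate_valdes_alpha(pairs, 375, phantom_library)
        assert cal.alpha_by_excitation["375"] == pytest.approx(0.55, abs=0.02)

    def test_single_pair_matches_adaptive_fit(self, noiseless_suite, phantom_library):
        rec = noiseless_suite[2]
        cal = calibrate_valdes_alpha([(rec.fluorescence, rec.reflectance)],
                                     rec.excitation_tag, phantom_library)
        res = fit_adaptive(rec.fluorescence, rec.reflectance, phantom_library)
        assert cal.alpha_by_excitation[rec.excitation_tag] == pytest.approx(
            res.alpha, abs=1e-3)

    def test_empty_pair_list_rejected(self, phantom_library):
        with pytest.raises(ValueError):
            calibrate_valdes_alpha([], 375, phantom_library)

    def test_round_trip_artifact(self, tmp_path, noiseless_suite, phantom_library):
        rec = noiseless_suite[0]
        cal = calibrate_valdes_alpha([(rec.fluorescence, rec.reflectance)],
                                     375, phantom_library)
        cal.to_json(tmp_path / "cal.json")
        back = fc.ValdesCalibration.from_json(tmp_path / "cal.json")
        assert back.alpha_by_excitation == cal.alpha_by_excitation


class TestOracle:
    def test_profile_minimum_at_true_alpha(self, noiseless_suite, phantom_library):
        rec = noiseless_suite[1]
        astar, alphas, costs = alpha_profile_oracle(rec.fluorescence, rec.reflectance,
                                                    phantom_library, grid_step=0.01)
        assert astar == pytest.approx(rec.spec.true_alpha, abs=0.01)
        assert costs.min() == costs[list(alphas).index(astar)]

    def test_profile_endpoint_equals_fixed_alpha_residual(self, noisy_suite,
                                                          phantom_library):
        rec = noisy_suite[0]
        _, alphas, costs = alpha_profile_oracle(rec.fluorescence, rec.reflectance,
                                               phantom_library, grid_step=0.1)
        kim = fit_fixed_alpha(rec.fluorescence, rec.reflectance, 1.0, phantom_library)
        assert costs[-1] == pytest.approx(kim.mse * kim.nobs, rel=1e-9)

    def test_invalid_grid_step_rejected(self, noisy_suite, phantom_library):
        rec = noisy_suite[0]
        with pytest.raises(ValueError):
            alpha_profile_oracle(rec.fluorescence, rec.reflectance,
                                 phantom_library, grid_step=0.5001)

    def test_adaptive_fit_matches_oracle_argmin(self, phantom_library, grid):
        """Oracle-equivalence on randomized noiseless instances."""
        rng = np.random.default_rng(42)
        for k in range(6):
            phantoms = make_suite_phantoms(k, noise_cv=0.0)
            ph = phantoms[int(rng.integers(0, 7))]
            fm = simulate_fluorescence(ph, phantom_library, grid, "405")
            r = simulate_reflectance(ph, grid)
            res = fit_adaptive(fm, r, phantom_library)
            astar, _, _ = alpha_profile_oracle(fm, r, phantom_library, grid_step=1e-2)
            assert abs(res.alpha - astar) <= 2e-2


class TestMultistart:
    def test_well_posed_instance_has_negligible_dispersion(self, noiseless_suite,
                                                           phantom_library):
        rec = noiseless_suite[2]
        report = multistart_robustness(rec.fluorescence, rec.reflectance,
                                       phantom_library, n_starts=20, seed=1)
        assert report["n_accepted"] >= 2
        assert report["alpha_dispersion"] < 1e-3
        assert max(report["fraction_dispersion"].values()) < 1e-3

    def test_single_start_has_zero_dispersion(self, noiseless_suite, phantom_library):
        rec = noiseless_suite[0]
        report = multistart_robustness(rec.fluorescence, rec.reflectance,
                                       phantom_library, n_starts=1, seed=0)
        if report["n_accepted"]:
            assert report["alpha_dispersion"] == 0.0

    def test_constant_reflectance_marked_not_applicable(self, grid):
        lib = two_basis_library(grid)
        a = lib.design_matrix(grid)
        fm = Spectrum(grid, a @ np.array([0.5, 0.5]), "fluorescence")
        r = Spectrum(grid, np.full(grid.shape, 0.7), "reflectance")
        report = multistart_robustness(fm, r, lib, n_starts=5, seed=0)
        assert report["alpha_identifiable"] is False
        assert report["alpha_dispersion"] is None


class TestFitOptions:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FitOptions(alpha_bounds=(0.5, 0.2))
        with pytest.raises(ValueError):
            FitOptions(residual_change_tol=0.0)
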