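"""Least-squares decomposition, reconstruction, error metrics, benchmark."""

import numpy as np
import pytest

import zernmp as z
from zernmp.fitting import CoefficientVector, _solve
from zernmp.map_io import MPMap
from zernmp.zernike_core import design_matrix, make_disk_grid


def field_from_coeffs(coeffs, grid, fill=0.0):
    vals = np.full((grid.size, grid.size), fill)
    vals[grid.mask] = design_matrix(grid, len(coeffs)) @ coeffs
    return MPMap(vals, grid.centre, grid.radius)


class TestFitZernike:
    def test_exact_recovery_of_known_vector(self, disk81):
        rng = np.random.default_rng(5)
        c = rng.uniform(-1, 1, 105)
        mp = field_from_coeffs(c, disk81)
        fit = z.fit_zernike(mp, 105)
        assert np.max(np.abs(fit.coefficients.values - c)) < 1e-8
        assert z.coefficient_hamming(c, fit.coefficients.values) == 0

    def test_constant_map_is_pure_piston(self):
        mp = MPMap(np.full((81, 81), 0.5))
        fit = z.fit_zernike(mp, 105)
        assert fit.coefficients.values[0] == pytest.approx(0.5, abs=1e-10)
        assert np.max(np.abs(fit.coefficients.values[1:])) < 1e-10

    def test_deterministic(self, disk81):
        rng = np.random.default_rng(9)
        mp = MPMap(rng.uniform(0, 1, (81, 81)))
        a = z.fit_zernike(mp, 50).coefficients.values
        b = z.fit_zernike(mp, 50).coefficients.values
        np.testing.assert_array_equal(a, b)

    def test_rank_deficient_design_raises(self):
        # 5x5 grid has fewer in-disk pixels than 105 columns
        mp = MPMap(np.zeros((5, 5)))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            z.fit_zernike(mp, 105)

    def test_monotone_residual_in_nested_models(self):
        manifest, maps, _ = z.make_cohort(1, seed=3)
        mp = maps[0]
        errs = [z.fit_zernike(mp, J).nrmse for J in (1, 3, 6, 15, 45, 105)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_linearity_of_least_squares(self, disk81):
        rng = np.random.default_rng(11)
        m1 = MPMap(rng.uniform(0, 1, (81, 81)))
        m2 = MPMap(rng.uniform(0, 1, (81, 81)))
        combo = MPMap(0.3 * m1.values + 0.6 * m2.values)
        c1 = z.fit_zernike(m1, 28).coefficients.values
        c2 = z.fit_zernike(m2, 28).coefficients.values
        cc = z.fit_zernike(combo, 28).coefficients.values
        np.testing.assert_allclose(cc, 0.3 * c1 + 0.6 * c2, atol=1e-10)

    def test_matches_brute_force_normal_equations(self):
        grid = make_disk_grid(15)
        rng = np.random.default_rng(2)
        mp = MPMap(rng.uniform(0, 1, (15, 15)))
        fit = z.fit_zernike(mp, 6)
        A = design_matrix(grid, 6, cache=False)
        y = mp.values[grid.mask]
        brute = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.coefficients.values, brute, atol=1e-10)

    def test_rotation_equivariance(self):
        # evaluate the same analytic field at rotated azimuth: m=0 terms
        # invariant, (cos, sin) pairs rotated by |m| * theta
        grid = make_disk_grid(81)
        rng = np.random.default_rng(21)
        c = rng.uniform(-1, 1, 28)
        theta = np.deg2rad(37.0)

        def eval_field(phi):
            vals = np.zeros((81, 81))
            acc = np.zeros(grid.n_unmasked)
            for j, cj in enumerate(c):
                acc += cj * z.basis_value(j, grid.rho, np.mod(phi, 2 * np.pi))
            vals[grid.mask] = acc
            return MPMap(vals)

        c0 = z.fit_zernike(eval_field(grid.phi), 28).coefficients.values
        c1 = z.fit_zernike(eval_field(grid.phi - theta), 28).coefficients.values
        for j in range(28):
            n, m = z.ansi_to_nm(j)
            if m == 0:
                assert abs(c1[j] - c0[j]) < 1e-6
            elif m > 0:
                js = z.ansi_index(n, -m)
                rot = np.array([[np.cos(m * theta), -np.sin(m * theta)],
                                [np.sin(m * theta), np.cos(m * theta)]])
                expect = rot @ np.array([c0[j], c0[js]])
                assert abs(c1[j] - expect[0]) < 1e-6
                assert abs(c1[js] - expect[1]) < 1e-6

    def test_convention_is_pure_permutation(self, disk81):
        manifest, maps, _ = z.make_cohort(1, seed=6)
        mp = maps[0]
        fa = z.fit_zernike(mp, 105, convention="ansi")
        fn = z.fit_zernike(mp, 105, convention="noll0")
        ra = z.reconstruct(fa.coefficients, disk81)
        rn = z.reconstruct(fn.coefficients, disk81)
        np.testing.assert_allclose(ra.values[disk81.mask],
                                   rn.values[disk81.mask], atol=1e-9)
        assert fa.nrmse == pytest.approx(fn.nrmse, abs=1e-12)


class TestReconstruct:
    def test_zero_coefficients_zero_map(self, disk81):
        mp = z.reconstruct(CoefficientVector(np.zeros(10)), disk81)
        assert np.all(mp.values[disk81.mask] == 0.0)
        assert np.all(np.isnan(mp.values[~disk81.mask]))

    def test_unit_piston_constant_one(self, disk81):
        mp = z.reconstruct(CoefficientVector([1.0]), disk81)
        np.testing.assert_array_equal(mp.values[disk81.mask], 1.0)

    def test_fit_reconstruct_nrmse_consistent(self):
        manifest, maps, _ = z.make_cohort(1, seed=8)
        mp = maps[0]
        fit = z.fit_zernike(mp, 105)
        recon = z.reconstruct(fit.coefficients, mp.grid())
        grid = mp.grid()
        direct = z.nrmse(mp.values[grid.mask], recon.values[grid.mask])
        assert direct == pytest.approx(fit.nrmse, abs=1e-12)

    def test_convention_mismatch_raises(self, disk81):
        cv = CoefficientVector(np.ones(5), convention="noll0")
        with pytest.raises(ValueError, match="convention"):
            z.reconstruct(cv, disk81, convention="ansi")


class TestNrmse:
    def test_identical_maps_zero(self):
        a = MPMap(np.random.default_rng(0).uniform(0, 1, (21, 21)))
        assert z.nrmse(a, a) == 0.0

    def test_constant_offset_closed_form(self):
        vals = np.linspace(0, 1, 81 * 81).reshape(81, 81)
        a = MPMap(vals)
        b = MPMap(vals + 0.1)
        # range of a over the disk is ~1; normalise exactly by it
        g = a.grid()
        rng_a = vals[g.mask].max() - vals[g.mask].min()
        assert z.nrmse(a, b) == pytest.approx(0.1 / rng_a)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, (2, 11, 11))
        expected = np.sqrt(np.mean((a - b) ** 2)) / (a.max() - a.min())
        assert z.nrmse(a, b) == pytest.approx(expected, abs=1e-14)

    def test_constant_reference_falls_back_to_max(self, caplog):
        a = np.full((9, 9), 0.5)
        b = a + 0.05
        with caplog.at_level("WARNING"):
            val = z.nrmse(a, b)
        assert val == pytest.approx(0.05 / 0.5)


class TestHamming:
    def test_identical_zero(self):
        c = np.array([0.5, -0.2, 0.1])
        assert z.coefficient_hamming(c, c) == 0

    def test_threshold_behaviour(self):
        c = np.array([1.0, 0.5, -0.25, 0.0])
        above = c.copy()
        above[2] += 0.02  # 2% of the max amplitude
        below = c.copy()
        below[3] += 0.005
        assert z.coefficient_hamming(c, above) == 1
        assert z.coefficient_hamming(c, below) == 0

    def test_scale_invariant_in_reference_units(self):
        c = np.array([2.0, 1.0])
        d = np.array([2.0, 1.03])  # diff 0.03 -> 0.015 after /2
        assert z.coefficient_hamming(c, d) == 1
        assert z.coefficient_hamming(c, d, tol=0.02) == 0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            z.coefficient_hamming(np.zeros(3), np.ones(3))


class TestEvaluateOptimizers:
    def test_least_squares_noise_free_is_exact(self):
        rep = z.evaluate_optimizers(n_trials=3, methods=("least_squares",),
                                    noise_frac=0.0, seed=1)
        assert rep.accuracy["least_squares"] < 1e-8
        assert rep.uniqueness["least_squares"] == 0.0

    def test_reproducible_per_seed(self):
        a = z.evaluate_optimizers(n_trials=3, methods=("least_squares",),
                                  seed=12)
        b = z.evaluate_optimizers(n_trials=3, methods=("least_squares",),
                                  seed=12)
        assert a.accuracy == b.accuracy
        assert a.robustness == b.robustness

    def test_all_methods_agree_on_small_problem(self):
        rep = z.evaluate_optimizers(
            n_trials=2, J=15, size=41, seed=2,
            methods=("least_squares", "quasi_newton", "levenberg_marquardt"))
        for m in rep.accuracy:
            assert rep.accuracy[m] < 1e-6
            assert rep.uniqueness[m] == 0.0

    def test_uniform_noise_model_selectable(self):
        rep = z.evaluate_optimizers(n_trials=2, J=15, size=41, seed=2,
                                    methods=("least_squares",),
                                    noise_model="uniform")
        assert rep.noise_model == "uniform"
        assert rep.robustness["least_squares"] >= 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            z.evaluate_optimizers(n_trials=1, methods=("newton_raphson",))
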