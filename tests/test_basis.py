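"""Basis evaluation, roughness penalties and penalized smoothing.

The B-spline evaluator is cross-checked against an independent Cox-de Boor
recursion; penalties against closed-form integrals; smoothing against a
direct normal-equations solve.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lordist import (
    BasisSystem,
    ConfigurationError,
    RankError,
    default_n_basis,
    eval_bspline_basis,
    eval_curve,
    eval_fourier_basis,
    gcv_lambda,
    roughness_penalty_matrix,
    smooth_trajectory,
)
from lordist.basis import _bspline_knots, quadrature_grid, trapezoid_weights


# -- independent oracle: textbook Cox-de Boor recursion ----------------------

def cox_de_boor(t, i, k, knots):
    """B_{i,k}(t) (order k, degree k-1) by the recursion, half-open spans
    with the conventional closure at the right end."""
    if k == 1:
        last = knots[i + 1] == knots[-1]
        if knots[i] <= t < knots[i + 1] or (last and t == knots[i + 1] and knots[i] < knots[i + 1]):
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[i + k - 1] - knots[i]
    if d1 > 0:
        out += (t - knots[i]) / d1 * cox_de_boor(t, i, k - 1, knots)
    d2 = knots[i + k] - knots[i + 1]
    if d2 > 0:
        out += (knots[i + k] - t) / d2 * cox_de_boor(t, i + 1, k - 1, knots)
    return out


class TestFourier:
    def test_row_at_zero(self):
        np.testing.assert_allclose(
            eval_fourier_basis(np.array([0.0]), 3, 10.0), [[1.0, 0.0, 1.0]]
        )

    def test_constant_basis(self):
        out = eval_fourier_basis(np.linspace(0, 5, 7), 1, 5.0)
        np.testing.assert_allclose(out, 1.0)

    def test_even_K_rejected_with_advice(self):
        with pytest.raises(ConfigurationError, match="odd"):
            eval_fourier_basis(np.array([0.0]), 4, 10.0)

    def test_harmonics_orthogonal_by_quadrature(self):
        T = 10.0
        grid = quadrature_grid(T)
        w = trapezoid_weights(grid)
        Phi = eval_fourier_basis(grid, 5, T)
        gram = (Phi * w[:, None]).T @ Phi
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8  # includes int sin*cos = 0

    def test_out_of_domain_rejected(self):
        with pytest.raises(ConfigurationError):
            eval_fourier_basis(np.array([11.0]), 3, 10.0)


class TestBspline:
    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_partition_of_unity(self, t):
        row = eval_bspline_basis(np.array([t]), 6, 10.0)
        assert abs(row.sum() - 1.0) < 1e-12
        assert (row >= -1e-12).all() and (row <= 1 + 1e-12).all()

    def test_clamped_left_endpoint(self):
        row = eval_bspline_basis(np.array([0.0]), 6, 10.0)[0]
        np.testing.assert_allclose(row, [1, 0, 0, 0, 0, 0], atol=1e-14)

    def test_K_below_order_rejected(self):
        with pytest.raises(ConfigurationError):
            eval_bspline_basis(np.array([0.0]), 3, 10.0, order=4)

    def test_against_cox_de_boor_oracle(self, rng):
        K, T, order = 7, 10.0, 4
        knots = _bspline_knots(K, T, order)
        ts = rng.uniform(0, T, size=50)
        ours = eval_bspline_basis(ts, K, T, order)
        ref = np.array(
            [[cox_de_boor(t, i, order, knots) for i in range(K)] for t in ts]
        )
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestPenalty:
    def test_fourier_constant_row_zero(self):
        b = BasisSystem.create("fourier", 5, 10.0)
        R = roughness_penalty_matrix(b)
        assert np.all(R[0] == 0) and np.all(R[:, 0] == 0)

    def test_fourier_closed_form_T_2pi(self):
        b = BasisSystem.create("fourier", 3, 2 * np.pi)
        R = roughness_penalty_matrix(b, penalty_order=2)
        np.testing.assert_allclose(R, np.diag([0.0, np.pi, np.pi]), atol=1e-12)

    @pytest.mark.parametrize("family,K", [("fourier", 7), ("bspline", 8)])
    def test_symmetric_psd(self, family, K):
        b = BasisSystem.create(family, K, 10.0)
        R = roughness_penalty_matrix(b)
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.linalg.eigvalsh(R).min() >= -1e-10


class TestSmoothing:
    @pytest.mark.parametrize("family,K", [("fourier", 5), ("bspline", 5)])
    @pytest.mark.parametrize("lam", [0.0, 1e-3, 10.0])
    def test_constant_data_fit_exactly(self, family, K, lam):
        # constants span both bases and incur no roughness penalty
        # (avoid t = T: the periodic Fourier basis repeats the t = 0 row)
        times = np.array([0.0, 2.0, 5.0, 7.5, 9.5])
        b = BasisSystem.create(family, K, 10.0)
        curve = smooth_trajectory(times, np.full(5, 5.0), b, lam)
        grid = np.linspace(0, 10, 101)
        np.testing.assert_allclose(eval_curve(curve, grid), 5.0, atol=1e-9)

    def test_interpolation_at_lambda_zero(self, rng):
        times = np.linspace(0, 9.5, 5)
        vals = rng.normal(size=5)
        b = BasisSystem.create("fourier", 5, 10.0)
        curve = smooth_trajectory(times, vals, b, 0.0)
        np.testing.assert_allclose(eval_curve(curve, times), vals, atol=1e-8)

    def test_duplicate_times_lambda_zero_is_rank_error(self):
        times = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        b = BasisSystem.create("fourier", 5, 10.0)
        with pytest.raises(RankError, match="lambda > 0"):
            smooth_trajectory(times, np.ones(5), b, 0.0)

    def test_matches_normal_equations_oracle(self):
        times = np.linspace(0, 10, 10)
        vals = 2 + 3 * times
        b = BasisSystem.create("bspline", 5, 10.0)
        curve = smooth_trajectory(times, vals, b, 0.0)
        Phi = b.evaluate(times)
        c_ref = np.linalg.solve(Phi.T @ Phi, Phi.T @ vals)  # independent solve
        np.testing.assert_allclose(
            eval_curve(curve, times), Phi @ c_ref, atol=1e-9
        )

    def test_roughness_monotone_in_lambda(self, rng):
        times = np.linspace(0, 10, 8)
        vals = np.sin(times) + rng.normal(0, 0.3, size=8)
        b = BasisSystem.create("bspline", 8, 10.0)
        R = roughness_penalty_matrix(b)
        rough = []
        for lam in [0.0, 1e-4, 1e-2, 1.0, 100.0]:
            c = smooth_trajectory(times, vals, b, lam).coefficients
            rough.append(float(c @ R @ c))
        assert all(a >= b_ - 1e-10 for a, b_ in zip(rough, rough[1:]))

    def test_infinite_smoothing_limits(self, rng):
        times = np.linspace(0, 10, 9)
        vals = rng.normal(2.0, 1.0, size=9)
        grid = np.linspace(0, 10, 51)
        # B-spline, p=2: approaches the OLS straight line
        bs = BasisSystem.create("bspline", 8, 10.0)
        fit = eval_curve(smooth_trajectory(times, vals, bs, 1e8), grid)
        slope, icpt = np.polyfit(times, vals, 1)
        np.testing.assert_allclose(fit, icpt + slope * grid, atol=1e-3)
        # Fourier: only the constant escapes the penalty -> best constant
        bf = BasisSystem.create("fourier", 5, 10.0)
        fitf = eval_curve(smooth_trajectory(times, vals, bf, 1e8), grid)
        np.testing.assert_allclose(fitf, vals.mean(), atol=1e-3)

    def test_scale_equivariance(self, rng):
        times = np.linspace(0, 10, 7)
        vals = rng.normal(size=7)
        b = BasisSystem.create("fourier", 5, 10.0)
        c1 = smooth_trajectory(times, vals, b, 0.01).coefficients
        c3 = smooth_trajectory(times, 3 * vals, b, 0.01).coefficients
        np.testing.assert_allclose(c3, 3 * c1, atol=1e-10)

    def test_gcv_prefers_smoothing_for_noisy_linear_data(self, rng):
        times = np.linspace(0, 10, 10)
        vals = 1 + 0.5 * times + rng.normal(0, 1.0, size=10)
        b = BasisSystem.create("bspline", 10, 10.0)
        lam = gcv_lambda(times, vals, b)
        assert lam > 1e-8  # saturated interpolation is rejected


class TestAutoK:
    def test_fourier_even_adjustment(self):
        assert default_n_basis(10, "fourier") == 9
        assert default_n_basis(9, "fourier") == 9
        assert default_n_basis(10, "bspline") == 10

    def test_basis_system_normalizes_even_fourier(self):
        assert BasisSystem.create("fourier", 10, 10.0).K == 9

    def test_bspline_order_capped_at_K(self):
        b = BasisSystem.create("bspline", 3, 10.0)
        assert b.spline_order == 3  # quadratic for 3 basis functions
        row = b.evaluate(np.array([5.0]))
        assert abs(row.sum() - 1.0) < 1e-12
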