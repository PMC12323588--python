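"""Basis systems and penalized least-squares trajectory smoothing.

Each subject-feature abundance trajectory x(t), observed at a handful of
irregular times on a common domain [0, T], is represented as a linear
combination of K fixed basis functions,

    x_hat(t) = sum_l c_l * phi_l(t),

with coefficients estimated by penalized least squares

    c = argmin ||x - Phi c||^2 + lambda * c' R c,

where R is the roughness penalty matrix of order-p derivatives,
R_ab = integral of phi_a^(p)(t) phi_b^(p)(t) dt.

Two families are supported:

* Fourier: 1, sin(h*w*t), cos(h*w*t) with w = 2*pi/T, so K is odd
  (a constant plus sine/cosine pairs).  Natural for periodic dynamics.
* B-spline: clamped uniform knots on [0, T], default cubic (order 4).
  Evaluation goes through scipy's B-spline design matrix; the roughness
  matrix is computed by trapezoid quadrature of derivative products.

The default number of basis functions follows the rule K = n_t (the
subject's number of observation times), which balances flexibility against
overfitting when each subject contributes only a few points; for Fourier an
even n_t is rounded down to the nearest odd K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.interpolate import BSpline

from ._errors import ConfigurationError, InsufficientDataError, RankError

_QUAD_POINTS = 1001  # trapezoid quadrature resolution used throughout


def quadrature_grid(T: float, n: int = _QUAD_POINTS) -> np.ndarray:
    return np.linspace(0.0, T, n)


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for an arbitrary sorted grid."""
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


# ---------------------------------------------------------------------------
# Raw basis evaluation
# ---------------------------------------------------------------------------


def eval_fourier_basis(
    times: np.ndarray, K: int, T: float, deriv: int = 0
) -> np.ndarray:
    """Evaluate the Fourier basis (1, sin(wt), cos(wt), sin(2wt), ...) at
    ``times``; ``deriv`` gives the order-``deriv`` derivative instead.

    K must be odd: the constant plus (K-1)/2 sine/cosine pairs.
    """
    times = np.asarray(times, dtype=float)
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if K % 2 == 0:
        raise ConfigurationError(
            f"Fourier basis needs an odd K, got {K}; use K-1 (the "
            "largest odd value), as the auto rule does"
        )
    if T <= 0:
        raise ConfigurationError("domain length T must be positive")
    if times.size and (times.min() < -1e-12 or times.max() > T + 1e-12):
        raise ConfigurationError("evaluation times outside the domain [0, T]")
    w = 2 * np.pi / T
    out = np.empty((times.size, K))
    out[:, 0] = 1.0 if deriv == 0 else 0.0
    for h in range(1, (K - 1) // 2 + 1):
        a = h * w
        phase = a * times + deriv * np.pi / 2  # d/dt sin(at) = a sin(at + pi/2)
        out[:, 2 * h - 1] = a**deriv * np.sin(phase)
        out[:, 2 * h] = a**deriv * np.cos(phase)
    return out


def _bspline_knots(K: int, T: float, order: int) -> np.ndarray:
    # clamped uniform knots: K - order interior knots equally spaced on (0, T)
    interior = np.linspace(0.0, T, K - order + 2)[1:-1]
    return np.concatenate([np.zeros(order), interior, np.full(order, T)])


def eval_bspline_basis(
    times: np.ndarray, K: int, T: float, order: int = 4, deriv: int = 0
) -> np.ndarray:
    """Evaluate K clamped uniform B-splines of the given order (degree
    order-1) at ``times``; ``deriv`` selects a derivative.

    Rows form a partition of unity (for deriv=0) and each basis function has
    local support.
    """
    times = np.asarray(times, dtype=float)
    if K < order:
        raise ConfigurationError(
            f"B-spline basis needs K >= order ({order}), got K={K}"
        )
    if T <= 0:
        raise ConfigurationError("domain length T must be positive")
    if times.size and (times.min() < -1e-12 or times.max() > T + 1e-12):
        raise ConfigurationError("evaluation times outside the domain [0, T]")
    knots = _bspline_knots(K, T, order)
    spl = BSpline(knots, np.eye(K), order - 1, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(np.clip(times, 0.0, T))
    return np.nan_to_num(np.asarray(out, dtype=float))


@dataclass(frozen=True)
class BasisSystem:
    """A fixed basis family on a common domain [0, T].

    Construction normalizes the configuration: for Fourier an even requested
    K is rounded down to the nearest odd value; for B-splines the order is
    capped at K so very short series (three time points) remain fittable.
    """

    family: str
    K: int
    T: float
    spline_order: int = 4
    penalty_order: int = 2

    @classmethod
    def create(
        cls,
        family: str,
        K: int,
        T: float,
        spline_order: int = 4,
        penalty_order: int = 2,
    ) -> "BasisSystem":
        if family not in ("fourier", "bspline"):
            raise ConfigurationError(f"unknown basis family {family!r}")
        if K < 1:
            raise ConfigurationError("K must be >= 1")
        if T <= 0:
            raise ConfigurationError("domain length T must be positive")
        if family == "fourier" and K % 2 == 0:
            K = K - 1
        if family == "bspline":
            spline_order = min(spline_order, K)
        return cls(family, int(K), float(T), int(spline_order), int(penalty_order))

    def evaluate(self, times: np.ndarray, deriv: int = 0) -> np.ndarray:
        if self.family == "fourier":
            return eval_fourier_basis(times, self.K, self.T, deriv=deriv)
        return eval_bspline_basis(
            times, self.K, self.T, order=self.spline_order, deriv=deriv
        )


def roughness_penalty_matrix(
    basis: BasisSystem, penalty_order: int | None = None
) -> np.ndarray:
    """R_ab = integral over [0,T] of the order-p derivatives of phi_a, phi_b.

    Closed form for Fourier (harmonics are orthogonal over full periods);
    trapezoid quadrature for B-splines.  Symmetric positive semi-definite.
    """
    p = basis.penalty_order if penalty_order is None else penalty_order
    if basis.family == "fourier":
        w = 2 * np.pi / basis.T
        diag = np.zeros(basis.K)
        for h in range(1, (basis.K - 1) // 2 + 1):
            val = (h * w) ** (2 * p) * basis.T / 2  # int sin^2 = int cos^2 = T/2
            diag[2 * h - 1] = val
            diag[2 * h] = val
        return np.diag(diag)
    grid = quadrature_grid(basis.T)
    D = basis.evaluate(grid, deriv=p)
    wq = trapezoid_weights(grid)
    R = (D * wq[:, None]).T @ D
    return 0.5 * (R + R.T)


@dataclass(frozen=True)
class SmoothedCurve:
    """A fitted trajectory: coefficient vector over a basis system."""

    coefficients: np.ndarray
    basis: BasisSystem
    subject_id: str | None = None
    feature_id: str | None = None

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        return eval_curve(self, grid)


def eval_curve(curve: SmoothedCurve, grid: np.ndarray) -> np.ndarray:
    """Evaluate the fitted curve sum_l c_l phi_l(t) on a grid in [0, T]."""
    return curve.basis.evaluate(np.asarray(grid, dtype=float)) @ curve.coefficients


# ---------------------------------------------------------------------------
# Penalized least squares
# ---------------------------------------------------------------------------


def penalized_smoother(
    times: np.ndarray, basis: BasisSystem, lam: float
) -> np.ndarray:
    """The K x n_t matrix S with c = S @ x solving the penalized normal
    equations (Phi'Phi + lambda R) c = Phi' x.

    Computed once per distinct time grid and reused across all features of a
    subject (and all subjects on an aligned design).
    """
    times = np.asarray(times, dtype=float)
    Phi = basis.evaluate(times)
    A = Phi.T @ Phi
    if lam > 0:
        A = A + lam * roughness_penalty_matrix(basis)
    else:
        if np.linalg.matrix_rank(Phi) < basis.K:
            raise RankError(
                "singular smoothing system at lambda=0 (duplicate times or "
                "K > number of distinct times); use lambda > 0"
            )
    try:
        c, low = sla.cho_factor(A)
        return sla.cho_solve((c, low), Phi.T)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, Phi.T, rcond=None)[0]
    except sla.LinAlgError:
        return np.linalg.lstsq(A, Phi.T, rcond=None)[0]


def smooth_trajectory(
    times: np.ndarray,
    values: np.ndarray,
    basis: BasisSystem,
    lam: float = 1e-8,
    subject_id: str | None = None,
    feature_id: str | None = None,
) -> SmoothedCurve:
    """Fit one trajectory by penalized least squares.

    Requires at least three observations; the default penalty
    ``lam = 1e-8`` is near-interpolating but keeps the normal equations
    well conditioned when K equals the number of time points.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise InsufficientDataError(
            f"need >= 3 observations to fit a trajectory, got {times.size}"
        )
    if times.shape != values.shape:
        raise ConfigurationError("times and values must have the same length")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    S = penalized_smoother(times, basis, lam)
    return SmoothedCurve(S @ values, basis, subject_id, feature_id)


_GCV_GRID = np.logspace(-8, 2, 11)


def gcv_lambda(
    times: np.ndarray,
    values: np.ndarray,
    basis: BasisSystem,
    grid: np.ndarray = _GCV_GRID,
) -> float:
    """Pick lambda minimizing generalized cross-validation,
    GCV(lam) = n ||(I-H)x||^2 / tr(I-H)^2, over a log-spaced grid."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    Phi = basis.evaluate(times)
    R = roughness_penalty_matrix(basis)
    n = times.size
    best, best_score = float(grid[0]), np.inf
    for lam in grid:
        A = Phi.T @ Phi + lam * R
        H = Phi @ np.linalg.solve(A, Phi.T)
        resid = values - H @ values
        denom = (n - np.trace(H)) ** 2
        if denom <= 0:
            continue
        score = n * float(resid @ resid) / denom
        if score < best_score:
            best, best_score = float(lam), score
    return best


def default_n_basis(n_t: int, family: str) -> int:
    """The K = n_t rule; Fourier takes the largest odd K <= n_t."""
    K = int(n_t)
    if family == "fourier" and K % 2 == 0:
        K -= 1
    return max(K, 1)
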