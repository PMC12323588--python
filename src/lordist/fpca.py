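"""Per-feature functional principal component analysis.

For one microbial feature, the smoothed subject trajectories
x_hat_1(t), ..., x_hat_n(t) are decomposed as

    x_hat_i(t) ~= mu(t) + sum_r xi_ir * psi_r(t),

where mu is the cross-subject mean function, the psi_r are orthonormal
eigenfunctions of the sample covariance operator, lambda_r the associated
eigenvalues (the variance of the scores xi_.r), and xi_ir the subject
scores.  The decomposition is computed on a discrete grid: curves are
evaluated on G equally spaced points, the covariance matrix is weighted by
trapezoid quadrature weights, symmetrized and eigendecomposed, and scores
are quadrature inner products of the centered curves with each
eigenfunction.

Orthonormality, score centering and the trace identity
sum_r lambda_r = integral of the pointwise sample variance
hold to quadrature accuracy and are asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ConfigurationError, InsufficientDataError
from .basis import SmoothedCurve, trapezoid_weights

DEFAULT_GRID_SIZE = 101
DEFAULT_VAR_THRESHOLD = 0.95


@dataclass(frozen=True)
class FeatureFPCA:
    """FPCA decomposition of one feature across subjects.

    ``eigenvalues``/``eigenfunctions``/``scores`` hold the R retained
    components; ``eigenvalues_all`` keeps the full computed spectrum so that
    variance fractions refer to the total variance.
    """

    feature_id: str | None
    grid: np.ndarray                 # (G,)
    mean: np.ndarray                 # (G,)
    eigenfunctions: np.ndarray       # (R, G), orthonormal under quadrature
    eigenvalues: np.ndarray          # (R,), non-increasing, >= 0
    scores: np.ndarray               # (n, R)
    subject_ids: tuple[str, ...]
    eigenvalues_all: np.ndarray      # full spectrum, clipped at 0

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues_all.sum())


def fit_fpca(
    curves: list[SmoothedCurve],
    grid_size: int = DEFAULT_GRID_SIZE,
    R: int | str = "auto",
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    feature_id: str | None = None,
) -> FeatureFPCA:
    """Fit FPCA to one feature's smoothed curves (one curve per subject).

    ``R="auto"`` retains the smallest number of components whose cumulative
    variance fraction reaches ``var_threshold`` (at least 1); an integer R
    fixes the count.
    """
    if len(curves) < 2:
        raise InsufficientDataError("FPCA needs at least 2 subjects")
    if grid_size < 10:
        raise ConfigurationError("grid_size must be >= 10")
    T = curves[0].basis.T
    for c in curves:
        if abs(c.basis.T - T) > 1e-12:
            raise ConfigurationError("all curves must share the domain [0, T]")
    grid = np.linspace(0.0, T, grid_size)
    values = np.vstack([c(grid) for c in curves])
    ids = tuple(c.subject_id or str(i) for i, c in enumerate(curves))
    return fpca_from_grid(
        values, grid, subject_ids=ids, R=R,
        var_threshold=var_threshold, feature_id=feature_id,
    )


def fpca_from_grid(
    values: np.ndarray,
    grid: np.ndarray,
    subject_ids: tuple[str, ...] | None = None,
    R: int | str = "auto",
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    feature_id: str | None = None,
) -> FeatureFPCA:
    """FPCA core on curves already evaluated on a common grid (n x G)."""
    values = np.asarray(values, dtype=float)
    n, G = values.shape
    if n < 2:
        raise InsufficientDataError("FPCA needs at least 2 subjects")
    if subject_ids is None:
        subject_ids = tuple(str(i) for i in range(n))

    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    mean = values.mean(axis=0)
    Xc = values - mean

    # quadrature-weighted sample covariance, symmetrized eigenproblem:
    # with C = Xc'Xc/(n-1), solve  W^{1/2} C W^{1/2} u = lambda u,
    # then psi = W^{-1/2} u is orthonormal under the quadrature inner product
    Y = Xc * sw  # (n, G)
    A = (Y.T @ Y) / (n - 1)
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    if evals.size and evals.min() < -1e-10 * max(1.0, abs(evals).max()):
        raise FloatingPointError(
            "covariance eigendecomposition produced a large negative eigenvalue"
        )
    evals = np.clip(evals, 0.0, None)

    n_keep_max = min(n - 1, G)
    evals_all = evals[:n_keep_max]

    if R == "auto":
        total = evals_all.sum()
        if total <= 0:
            R_eff = 1
        else:
            cum = np.cumsum(evals_all) / total
            R_eff = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
            R_eff = max(1, min(R_eff, n_keep_max))
    else:
        R_eff = int(R)
        if R_eff < 1:
            raise ConfigurationError("R must be >= 1")
        R_eff = min(R_eff, n_keep_max)

    with np.errstate(divide="ignore", invalid="ignore"):
        psi = (evecs[:, :R_eff] / sw[:, None]).T  # (R, G)
    psi = np.nan_to_num(psi)

    # deterministic sign: quadrature integral >= 0, tie-break on first value
    integrals = psi @ w
    for r in range(R_eff):
        s = integrals[r]
        if s < -1e-12 or (abs(s) <= 1e-12 and psi[r, 0] < 0):
            psi[r] = -psi[r]

    scores = (Xc * w) @ psi.T  # (n, R)

    return FeatureFPCA(
        feature_id=feature_id,
        grid=grid,
        mean=mean,
        eigenfunctions=psi,
        eigenvalues=evals_all[:R_eff].copy(),
        scores=scores,
        subject_ids=tuple(subject_ids),
        eigenvalues_all=evals_all.copy(),
    )


def variance_explained(fpca: FeatureFPCA) -> np.ndarray:
    """Fraction of total variance per retained component,
    lambda_r / sum over all computed components.

    Returns zeros (degenerate feature, e.g. identical curves) when the total
    variance is 0.
    """
    total = fpca.eigenvalues_all.sum()
    if total <= 0:
        return np.zeros_like(fpca.eigenvalues)
    return fpca.eigenvalues / total
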