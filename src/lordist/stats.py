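"""Ordination and permutation testing on distance matrices.

Two classical tools evaluate whether a distance matrix separates phenotype
groups:

* Principal coordinates analysis (classical multidimensional scaling):
  eigendecomposition of the double-centered squared-distance (Gower)
  matrix B = -1/2 J A J, A = D^2, J = I - 11'/n.  Coordinates are
  eigenvectors scaled by the square root of their (non-negative)
  eigenvalues.  Negative eigenvalues are reported, not corrected, because
  the distances produced by this package are Euclidean by construction;
  Cailliez and Lingoes corrections are available for external matrices.

* PERMANOVA: the pseudo-F statistic

      F = (SS_A / (a - 1)) / (SS_W / (N - a)),

  with SS_T = (1/N) sum_{i<i'} D_ii'^2,
  SS_W = sum_g (1/n_g) sum_{i<i' in g} D_ii'^2, SS_A = SS_T - SS_W,
  and a permutation null from uniformly random relabelings.  The p-value
  uses the "+1 rule" p = (1 + #{F* >= F_obs}) / (1 + n_perm), so the
  smallest attainable p at 999 permutations is 0.001.  For tiny designs an
  exhaustive mode enumerates every distinct labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._errors import ConfigurationError, ValidationError
from .distance import DistanceMatrix


@dataclass(frozen=True)
class PcoaResult:
    coordinates: np.ndarray      # (n, k)
    eigenvalues: np.ndarray      # (n - 1,), non-increasing
    negative_fraction: float     # |sum of negative eigenvalues| / sum |eigenvalues|


@dataclass(frozen=True)
class PermanovaResult:
    F: float
    p: float
    n_perm: int
    a: int
    N: int
    seed: int | None

    def __str__(self) -> str:  # CLI-friendly one-liner
        return (
            f"PERMANOVA: F = {self.F:.6g}, p = {self.p:.6g} "
            f"({self.a} groups, N = {self.N}, {self.n_perm} permutations)"
        )


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def pcoa(D: DistanceMatrix, k: int = 2, correction: str | None = None) -> PcoaResult:
    """Classical principal coordinates of a distance matrix.

    ``correction`` may be ``"cailliez"`` or ``"lingoes"`` to make an
    external non-Euclidean matrix embeddable; the default applies none.
    Coordinates for non-positive eigenvalues are zero-filled.
    """
    n = D.n
    if n < 3:
        raise ConfigurationError("PCoA needs at least 3 subjects")
    if k > n - 1:
        raise ConfigurationError(f"k={k} exceeds the maximum of n-1={n - 1} axes")
    values = D.values
    if correction is not None:
        evals_raw = np.linalg.eigvalsh(_gower_center(values))
        neg = evals_raw.min()
        if neg < -1e-12:
            off = ~np.eye(n, dtype=bool)
            if correction == "cailliez":
                # smallest c with D + c (off-diagonal) Euclidean; standard
                # companion-eigenvalue construction on (Delta1, Delta2)
                B1 = _gower_center(values)              # -1/2 J D^2 J
                B2 = _gower_center_from_sq(values)      # -1/2 J D J
                upper = np.block([[np.zeros((n, n)), 2 * B1],
                                  [-np.eye(n), -4 * B2]])
                c = float(np.max(np.real(np.linalg.eigvals(upper))))
                values = values + np.where(off, c, 0.0)
            elif correction == "lingoes":
                c = float(-neg)
                values = np.sqrt(np.where(off, values**2 + 2 * c, 0.0))
            else:
                raise ConfigurationError(f"unknown correction {correction!r}")
    B = _gower_center(values)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if evals[axis] > 0:
            coords[:, axis] = evecs[:, axis] * np.sqrt(evals[axis])
    abs_sum = np.abs(evals).sum()
    neg_frac = float(np.abs(evals[evals < 0]).sum() / abs_sum) if abs_sum > 0 else 0.0
    return PcoaResult(coords, evals[: n - 1], neg_frac)


def _gower_center_from_sq(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _pseudo_f(D2: np.ndarray, masks: np.ndarray, ss_t: float) -> float:
    """F for one labeling; masks is (a, N) boolean."""
    N = D2.shape[0]
    a = masks.shape[0]
    ss_w = 0.0
    for g in range(a):
        idx = masks[g]
        ng = idx.sum()
        ss_w += D2[np.ix_(idx, idx)].sum() / (2 * ng)
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        return np.inf
    return (ss_a / (a - 1)) / (ss_w / (N - a))


def permanova(
    D: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA of group labels on a distance matrix.

    ``labels`` is either a sequence aligned to ``D.subject_ids`` or a
    mapping subject -> label.  ``method="exact"`` enumerates all distinct
    labelings (two-group designs) instead of sampling permutations.

    With a fixed seed the permutation stream, hence F and p, are exactly
    reproducible.  A degenerate matrix with zero within-group sum of
    squares yields F = +inf with p still computed from permutations.
    """
    if isinstance(labels, dict):
        labels = [labels[s] for s in D.subject_ids]
    labels = np.asarray([str(x) for x in labels])
    N = D.n
    if labels.size != N:
        raise ConfigurationError("labels must align with D.subject_ids")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")

    D2 = D.values**2
    ss_t = D2.sum() / (2 * N)
    masks = np.vstack([inv == g for g in range(a)])
    f_obs = _pseudo_f(D2, masks, ss_t)

    if method == "exact":
        if a != 2:
            raise ConfigurationError("exact enumeration supports 2 groups")
        n1 = int(masks[0].sum())
        count, total = 0, 0
        for comb in combinations(range(N), n1):
            m = np.zeros(N, dtype=bool)
            m[list(comb)] = True
            f_star = _pseudo_f(D2, np.vstack([m, ~m]), ss_t)
            total += 1
            if f_star >= f_obs:
                count += 1
        return PermanovaResult(float(f_obs), count / total, total, a, N, None)

    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorized permutations: (n_perm, N) permuted group indices
    perm_idx = np.argsort(rng.random((n_perm, N)), axis=1)
    inv_perm = inv[perm_idx]  # permuted labels
    ss_w_perm = np.zeros(n_perm)
    for g in range(a):
        P = (inv_perm == g).astype(float)  # (n_perm, N)
        ng = masks[g].sum()
        ss_w_perm += np.einsum("pi,pi->p", P @ D2, P) / (2 * ng)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = ((ss_t - ss_w_perm) / (a - 1)) / (ss_w_perm / (N - a))
    f_star = np.where(ss_w_perm <= 0, np.inf, f_star)
    n_ge = int(np.sum(f_star >= f_obs))
    p = (1 + n_ge) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), int(n_perm), a, N, seed)
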