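"""Eigenvalue-weighted FPC distances and the end-to-end pipeline.

For each feature j, the dissimilarity between subjects S_i and S_i' is the
eigenvalue-weighted Euclidean distance between their FPCA score vectors,

    d_j(S_i, S_i') = ( sum_r lambda_jr * (xi_ijr - xi_i'jr)^2 )^(1/2),

i.e. the ordinary Euclidean distance after scaling score component r by
sqrt(lambda_jr).  Feature distances are aggregated across the m features in
a Euclidean framework,

    D(S_i, S_i') = ( sum_j d_j(S_i, S_i')^2 )^(1/2),

so the final n x n subject distance matrix is itself Euclidean (each subject
embeds as the concatenation of its sqrt(lambda)-scaled score vectors), which
guarantees non-negative principal-coordinate eigenvalues downstream.

:func:`lordist` runs the whole chain on a longitudinal table: per
subject-feature penalized smoothing, per-feature FPCA, per-feature
distances, aggregation.  All features are treated equally; an optional
weight vector multiplying the squared feature distances is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from ._errors import ConfigurationError, InsufficientDataError, ValidationError
from .basis import BasisSystem, default_n_basis, gcv_lambda, penalized_smoother
from .fpca import (
    DEFAULT_GRID_SIZE,
    DEFAULT_VAR_THRESHOLD,
    FeatureFPCA,
    fpca_from_grid,
    variance_explained,
)
from .io import LongitudinalTable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative subject-by-subject distance matrix."""

    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.subject_ids):
            raise ValidationError("subject_ids length does not match matrix")
        if not np.isfinite(v).all():
            raise ValidationError("non-finite distance entry")
        if np.abs(v - v.T).max(initial=0.0) > 1e-9:
            raise ValidationError("distance matrix not symmetric within 1e-9")
        if (v < 0).any():
            raise ValidationError("negative distance entry")
        object.__setattr__(self, "values", 0.5 * (v + v.T))
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def reorder(self, subject_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return DistanceMatrix(list(subject_ids), self.values[np.ix_(idx, idx)])


def feature_distance(fpca: FeatureFPCA) -> DistanceMatrix:
    """All-pairs weighted FPC distance for one feature: Euclidean distance
    between subjects' score vectors scaled componentwise by sqrt(lambda)."""
    scaled = fpca.scores * np.sqrt(fpca.eigenvalues)
    D = squareform(pdist(scaled, metric="euclidean"))
    return DistanceMatrix(list(fpca.subject_ids), D)


def aggregate_distances(
    per_feature: Sequence[DistanceMatrix],
    weights: Sequence[float] | None = None,
) -> DistanceMatrix:
    """Root-sum-of-squares aggregation of per-feature distance matrices.

    Optional non-negative weights multiply the squared feature distances
    (default: all 1, i.e. every feature contributes equally).
    """
    if not per_feature:
        raise ConfigurationError("need at least one feature distance matrix")
    ids = per_feature[0].subject_ids
    for dm in per_feature[1:]:
        if dm.subject_ids != ids:
            raise ConfigurationError(
                "feature distance matrices have mismatched subject sets"
            )
    if weights is None:
        weights = np.ones(len(per_feature))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(per_feature) or (weights < 0).any():
        raise ConfigurationError("weights must be non-negative, one per feature")
    total = np.zeros_like(per_feature[0].values)
    for wj, dm in zip(weights, per_feature):
        total += wj * dm.values**2
    return DistanceMatrix(list(ids), np.sqrt(total))


@dataclass
class RunReport:
    """Per-run diagnostics from the pipeline."""

    n_subjects: int = 0
    n_features: int = 0
    config: dict = field(default_factory=dict)
    feature_components: dict[str, int] = field(default_factory=dict)
    feature_variance_explained: dict[str, list[float]] = field(default_factory=dict)
    zero_variance_features: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
            "config": self.config,
            "feature_components": self.feature_components,
            "feature_variance_explained": self.feature_variance_explained,
            "zero_variance_features": self.zero_variance_features,
            "warnings": self.warnings,
        }


def lordist(
    table: LongitudinalTable,
    basis: str = "fourier",
    n_basis: int | str = "auto",
    lam: float | str = 1e-8,
    spline_order: int = 4,
    penalty_order: int = 2,
    grid_size: int = DEFAULT_GRID_SIZE,
    components: int | str = "auto",
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    feature_weights: dict[str, float] | None = None,
    keep_fpca: bool = True,
) -> tuple[DistanceMatrix, list[FeatureFPCA], RunReport]:
    """Run the full pipeline: smoothing -> per-feature FPCA -> distances.

    Parameters
    ----------
    table:
        Longitudinal observations on a common domain [0, T].  Subjects must
        have at least three distinct observation times (apply
        :func:`lordist.io.require_min_timepoints` first on real data).
    basis, n_basis, lam:
        Basis family, number of basis functions (``"auto"`` = the subject's
        number of time points, Fourier rounded down to odd) and smoothing
        penalty (``"gcv"`` selects it per subject by generalized
        cross-validation).
    components:
        Retained FPCA components per feature; ``"auto"`` keeps the smallest
        number reaching ``var_threshold`` cumulative variance.
    feature_weights:
        Optional map feature -> non-negative weight on the squared feature
        distance; missing features default to 1.
    keep_fpca:
        When False the per-feature FPCA objects are discarded to save
        memory; an empty list is returned in their place.

    Returns
    -------
    (DistanceMatrix, list of FeatureFPCA, RunReport)

    Notes
    -----
    A feature that was never recorded at some of a subject's sampled times
    is treated as 0 there (not detected), which keeps the subject set
    identical across features as the aggregation formula requires.
    """
    subjects = table.subjects
    features = table.features
    if len(subjects) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    if len(features) < 1:
        raise InsufficientDataError("need at least 1 feature")
    T = table.T
    grid = np.linspace(0.0, T, grid_size)

    # wide view: one row per (subject, time), one column per feature, 0-filled
    wide = table.data.pivot_table(
        index=["subject", "time"], columns="feature", values="value", fill_value=0.0
    ).reindex(columns=features)
    feat_values = wide.to_numpy()  # (total samples, m)
    sub_of_row = wide.index.get_level_values(0).to_numpy()
    time_of_row = wide.index.get_level_values(1).to_numpy(dtype=float)

    m = len(features)
    n = len(subjects)
    # curves evaluated on the common grid, per subject then per feature
    curves = np.empty((m, n, grid_size))
    smoother_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    for si, subj in enumerate(subjects):
        rows = np.flatnonzero(sub_of_row == subj)
        times = time_of_row[rows]
        order = np.argsort(times)
        rows, times = rows[order], times[order]
        n_t = times.size
        if n_t < 3:
            raise InsufficientDataError(
                f"subject {subj} has {n_t} time point(s); at least 3 required"
            )
        key = tuple(np.round(times, 12))
        if key not in smoother_cache:
            K = default_n_basis(n_t, basis) if n_basis == "auto" else int(n_basis)
            K = min(K, n_t)  # keep the lambda=0 system well-posed
            bs = BasisSystem.create(
                basis, K, T, spline_order=spline_order, penalty_order=penalty_order
            )
            if lam == "gcv":
                # representative series: per-time mean across features
                lam_s = gcv_lambda(times, feat_values[rows].mean(axis=1), bs)
            else:
                lam_s = float(lam)
            S = penalized_smoother(times, bs, lam_s)  # (K, n_t)
            Phi_grid = bs.evaluate(grid)  # (G, K)
            smoother_cache[key] = (Phi_grid @ S, None)  # (G, n_t)
        proj = smoother_cache[key][0]
        # all m features of this subject at once: (G, n_t) @ (n_t, m)
        curves[:, si, :] = (proj @ feat_values[rows]).T

    report = RunReport(
        n_subjects=n,
        n_features=m,
        config={
            "basis": basis,
            "n_basis": n_basis,
            "lambda": lam,
            "spline_order": spline_order,
            "penalty_order": penalty_order,
            "grid_size": grid_size,
            "components": components,
            "var_threshold": var_threshold,
        },
    )

    wvec = np.ones(m)
    if feature_weights is not None:
        for j, f in enumerate(features):
            wvec[j] = feature_weights.get(f, 1.0)
        if (wvec < 0).any():
            raise ConfigurationError("feature weights must be non-negative")

    total_sq = np.zeros((n, n))
    fpcas: list[FeatureFPCA] = []
    for j, feat in enumerate(features):
        fp = fpca_from_grid(
            curves[j], grid, subject_ids=tuple(subjects),
            R=components, var_threshold=var_threshold, feature_id=feat,
        )
        if fp.total_variance <= 0:
            report.zero_variance_features.append(feat)
        report.feature_components[feat] = fp.n_components
        report.feature_variance_explained[feat] = [
            float(v) for v in variance_explained(fp)
        ]
        scaled = fp.scores * np.sqrt(fp.eigenvalues)
        total_sq += wvec[j] * squareform(pdist(scaled, metric="sqeuclidean"))
        if keep_fpca:
            fpcas.append(fp)

    D = DistanceMatrix(list(subjects), np.sqrt(np.maximum(total_sq, 0.0)))
    return D, fpcas, report
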