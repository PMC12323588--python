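"""Input/output and preprocessing for longitudinal abundance tables.

The central container is :class:`LongitudinalTable`: a long-format record of
observations ``(subject, feature, time, value)`` over a common time domain
``[0, T]``, optionally carrying a subject → group map.  Values are counts or
relative abundances; a recorded 0 is an observation (e.g. a taxon that was
not detected), while a missing time point is simply absent from the table.

Preprocessing follows the usual microbiome pipeline: total-sum scaling to
relative abundances, a minimum-total-count feature filter, a
prevalence/abundance feature filter, and a minimum-time-points-per-subject
rule (trajectory fitting needs at least three observation times).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import (
    DuplicateKeyError,
    FormatError,
    JoinError,
    ValidationError,
)

_COLUMNS = ["subject", "time", "feature", "value"]


@dataclass(frozen=True)
class LongitudinalTable:
    """Irregular longitudinal observations of many features on many subjects.

    Parameters
    ----------
    data:
        Long-format frame with columns ``subject``, ``time``, ``feature``,
        ``value``.  Keys ``(subject, feature, time)`` are unique.
    T:
        Right end of the common time domain ``[0, T]``.  Defaults to the
        maximum observed time.
    groups:
        Optional map from subject ID to group label.
    dropped_subjects:
        Subjects removed by :func:`require_min_timepoints` (report only).
    """

    data: pd.DataFrame
    T: float
    groups: dict[str, str] | None = None
    dropped_subjects: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_frame(
        cls,
        data: pd.DataFrame,
        T: float | None = None,
        groups: dict[str, str] | None = None,
    ) -> "LongitudinalTable":
        """Validate a long-format frame and wrap it.

        Checks the container invariants: unique keys, finite non-negative
        values, times within ``[0, T]``.
        """
        missing = [c for c in _COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        data = data.loc[:, _COLUMNS].copy()
        data["subject"] = data["subject"].astype(str)
        data["feature"] = data["feature"].astype(str)
        data["time"] = pd.to_numeric(data["time"], errors="raise")
        data["value"] = pd.to_numeric(data["value"], errors="raise")

        if not np.isfinite(data[["time", "value"]].to_numpy()).all():
            raise ValidationError("non-finite time or value encountered")
        if (data["value"] < 0).any():
            bad = data.loc[data["value"] < 0].iloc[0]
            raise ValidationError(
                f"negative value {bad['value']} for subject {bad['subject']}, "
                f"feature {bad['feature']} at t={bad['time']}"
            )
        if (data["time"] < 0).any():
            raise ValidationError("negative time encountered")

        dup = data.duplicated(subset=["subject", "feature", "time"])
        if dup.any():
            row = data.loc[dup].iloc[0]
            raise DuplicateKeyError(
                "duplicate (subject, feature, time) key: "
                f"({row['subject']}, {row['feature']}, {row['time']})"
            )

        t_max = float(data["time"].max()) if len(data) else 0.0
        if T is None:
            T = t_max
        if len(data) and t_max > T:
            raise ValidationError(f"observed time {t_max} exceeds domain end T={T}")
        data = data.reset_index(drop=True)
        return cls(data=data, T=float(T), groups=groups)

    # -- convenience accessors -------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature"].unique())

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def subject_times(self, subject: str) -> np.ndarray:
        """Sorted distinct observation times of one subject (all features)."""
        t = self.data.loc[self.data["subject"] == subject, "time"].unique()
        return np.sort(t)

    def with_groups(self, groups: dict[str, str]) -> "LongitudinalTable":
        return replace(self, groups=dict(groups))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def read_long_table(path, dialect: str = "tsv") -> LongitudinalTable:
    """Read a long-format table with header subject/time/feature/value.

    Header matching is case-insensitive; lines starting with ``#`` are
    ignored.
    """
    df = pd.read_csv(path, sep=_sep(dialect), comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return LongitudinalTable.from_frame(df)


def write_long_table(table: LongitudinalTable, path, dialect: str = "tsv") -> None:
    """Write a long-format table; values keep full precision (17 sig. digits)."""
    table.data.to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")


def read_wide_table(matrix_path, metadata_path) -> LongitudinalTable:
    """Read a sample-by-feature matrix plus metadata mapping samples to
    (subject, time, group).

    Each matrix row becomes one observation per feature at that sample's
    time.  Group labels from the metadata are attached to the table.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    meta.columns = [str(c).strip().lower() for c in meta.columns]
    for col in ("sample", "subject", "time"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing column: {col}")
    meta = meta.set_index(meta["sample"].astype(str))

    missing = [s for s in mat.index.astype(str) if s not in meta.index]
    if missing:
        raise JoinError(f"sample(s) absent from metadata: {', '.join(missing[:5])}")

    values = mat.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("non-numeric cell in abundance matrix")

    long = mat.stack().reset_index()
    long.columns = ["sample", "feature", "value"]
    long["sample"] = long["sample"].astype(str)
    long["subject"] = meta.loc[long["sample"], "subject"].astype(str).to_numpy()
    long["time"] = meta.loc[long["sample"], "time"].to_numpy()

    groups = None
    if "group" in meta.columns:
        groups = {
            str(r["subject"]): str(r["group"]) for _, r in meta.iterrows()
        }
    return LongitudinalTable.from_frame(long[_COLUMNS], groups=groups)


def to_wide(table: LongitudinalTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`read_wide_table` (in-memory): returns the
    sample-by-feature matrix and the metadata frame.

    Samples are named ``<subject>@<time>``.  Feature cells that were never
    observed for a sample come back as 0.
    """
    df = table.data.copy()
    df["sample"] = df["subject"] + "@" + df["time"].astype(str)
    mat = df.pivot(index="sample", columns="feature", values="value").fillna(0.0)
    meta = (
        df[["sample", "subject", "time"]]
        .drop_duplicates("sample")
        .set_index("sample")
        .reset_index()
    )
    if table.groups is not None:
        meta["group"] = meta["subject"].map(table.groups)
    return mat, meta


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------


def tss_normalize(table: LongitudinalTable) -> LongitudinalTable:
    """Total-sum scaling: divide each (subject, time) sample by its total.

    After normalization every sample's values sum to 1.  Raises on an
    all-zero sample, which has no defined composition.
    """
    df = table.data.copy()
    totals = df.groupby(["subject", "time"])["value"].transform("sum")
    zero = totals <= 0
    if zero.any():
        row = df.loc[zero].iloc[0]
        raise ValidationError(
            f"all-zero sample: subject {row['subject']} at t={row['time']}"
        )
    df["value"] = df["value"] / totals
    return replace(table, data=df)


def filter_low_count_features(
    table: LongitudinalTable, min_total: int = 5
) -> LongitudinalTable:
    """Drop features whose total count over all observations is < ``min_total``."""
    totals = table.data.groupby("feature")["value"].sum()
    keep = set(totals.index[totals >= min_total])
    df = table.data[table.data["feature"].isin(keep)].reset_index(drop=True)
    return replace(table, data=df)


def filter_low_abundance_features(
    table: LongitudinalTable, min_rel: float = 1e-4, max_frac: float = 0.9
) -> LongitudinalTable:
    """Prevalence/abundance filter on relative abundances.

    A feature is removed iff its relative abundance is below ``min_rel`` in
    strictly more than ``max_frac`` of the (subject, time) samples.  Samples
    where the feature was not recorded count as abundance 0.
    """
    vals = table.data["value"]
    if (vals < 0).any() or (vals > 1).any():
        raise ValidationError(
            "values outside [0, 1]; run tss_normalize first to obtain "
            "relative abundances"
        )
    df = table.data
    n_samples = df[["subject", "time"]].drop_duplicates().shape[0]
    # per feature: number of samples at/above threshold (unrecorded => 0 => below)
    above = (
        df[df["value"] >= min_rel].groupby("feature")["value"].size()
    )
    features = df["feature"].unique()
    n_above = pd.Series(0, index=features, dtype=float)
    n_above.loc[above.index] = above
    frac_below = (n_samples - n_above) / n_samples
    keep = set(frac_below.index[frac_below <= max_frac])
    out = df[df["feature"].isin(keep)].reset_index(drop=True)
    return replace(table, data=out)


def require_min_timepoints(
    table: LongitudinalTable, min_k: int = 3
) -> LongitudinalTable:
    """Drop subjects observed at fewer than ``min_k`` distinct times.

    Functional smoothing needs at least three time points per subject; the
    dropped subject IDs are recorded on the returned table.
    """
    counts = table.data.groupby("subject")["time"].nunique()
    dropped = sorted(counts.index[counts < min_k])
    df = table.data[~table.data["subject"].isin(dropped)].reset_index(drop=True)
    groups = table.groups
    if groups is not None:
        groups = {s: g for s, g in groups.items() if s not in dropped}
    return replace(
        table,
        data=df,
        groups=groups,
        dropped_subjects=table.dropped_subjects + tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Distance-matrix TSV round trip
# ---------------------------------------------------------------------------


def write_distance_matrix(dm, path) -> None:
    """Write a square distance matrix as TSV with subject IDs on both axes."""
    df = pd.DataFrame(dm.values, index=dm.subject_ids, columns=dm.subject_ids)
    df.to_csv(path, sep="\t", index_label="subject", float_format="%.17g")


def read_distance_matrix(path):
    """Read a square TSV distance matrix, validating symmetry (1e-9),
    zero diagonal and non-negativity."""
    from .distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValidationError("row and column subject IDs differ")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("non-finite distance entry")
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetric distances for pair ({df.index[i]}, {df.index[j]})"
        )
    if (values < 0).any():
        i, j = np.unravel_index(np.argmin(values), values.shape)
        raise ValidationError(
            f"negative distance for pair ({df.index[i]}, {df.index[j]})"
        )
    if np.abs(np.diag(values)).max(initial=0.0) > 1e-12:
        raise ValidationError("nonzero diagonal")
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(subject_ids=list(df.index.astype(str)), values=values)
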