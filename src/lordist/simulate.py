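"""Synthetic longitudinal microbiome benchmark generator.

The generator emulates a two-phenotype longitudinal study: 100 subjects
(50 cases, 50 controls) sampled at 10 time points on [0, 10] across 200
microbial features.  Each feature is randomly assigned to one of three
taxon archetypes whose mean trajectories differ between groups in
increasingly subtle ways, with Gaussian noise whose variance reflects the
taxon's abundance scale:

1. constant, high abundance, identical in both groups:
       x(t) = 10 + e1,                       e1 ~ N(0, 3)
2. periodic, intermediate abundance, case amplitude inflated by a sigmoid
   term:
       control: x(t) = 10 (sin(pi t + pi/2) + 10) + e2
       case:    x(t) = 10 (pi/(1+exp(-t)) + 4 sin(pi t + pi/2) + 10) + e2
       e2 ~ N(0, 5)
3. low abundance, constant in controls, sigmoidal rise in cases:
       control: x(t) = 30 + e3
       case:    x(t) = 40 (1/(1+exp(-(t-5))) + 0.25) + e3,   e3 ~ N(0, 9)

N(0, v) denotes mean 0 and *variance* v.  Simulated values are clipped at 0
(abundances are non-negative); with these trajectory scales the clip
essentially never binds, so the injected sparsity zeros dominate.

Time grids are either aligned (all subjects share n_t evenly spaced points
spanning [0, 10]) or misaligned (each subject independently draws one
uniform time per equal subinterval, giving irregular but covering
schedules); a pure-uniform mode is also available.  Sparsity is injected by
setting an exact fraction of the observed values to zero, drawn uniformly
without replacement — zeros remain observations, they are not missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .io import LongitudinalTable


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic benchmark; defaults are the study design
    described in the module docstring."""

    n_case: int = 50
    n_control: int = 50
    n_timepoints: int = 10
    n_features: int = 200
    domain: tuple[float, float] = (0.0, 10.0)
    sparsity: float = 0.0
    time_mode: str = "aligned"          # aligned | misaligned | uniform
    noise_variances: tuple[float, float, float] = (3.0, 5.0, 9.0)
    taxon_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    taxon2_variant: str = "literal"     # literal | amplitude
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if not (0.0 <= self.sparsity < 1.0):
            raise ConfigurationError("sparsity must lie in [0, 1)")
        if abs(sum(self.taxon_probs) - 1.0) > 1e-9:
            raise ConfigurationError("taxon_probs must sum to 1")
        if self.time_mode not in ("aligned", "misaligned", "uniform"):
            raise ConfigurationError(f"unknown time_mode {self.time_mode!r}")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")


# ---------------------------------------------------------------------------
# Taxon mean trajectories
# ---------------------------------------------------------------------------


def taxon1_mean(t, group: str = "case"):
    """Constant high-abundance taxon, identical in both groups."""
    return np.full_like(np.asarray(t, dtype=float), 10.0)


def taxon2_mean(t, group: str, variant: str = "literal"):
    """Periodic intermediate-abundance taxon; the case group gains a
    sigmoid term (literal form) or a sigmoid-modulated amplitude."""
    t = np.asarray(t, dtype=float)
    osc = np.sin(np.pi * t + 0.5 * np.pi)
    if group == "control":
        return 10.0 * (osc + 10.0)
    sig = np.pi / (1.0 + np.exp(-t))
    if variant == "literal":
        return 10.0 * (sig + 4.0 * osc + 10.0)
    if variant == "amplitude":
        return 10.0 * (sig * 4.0 * osc + 10.0)
    raise ConfigurationError(f"unknown taxon-2 variant {variant!r}")


def taxon3_mean(t, group: str):
    """Low-abundance taxon: flat in controls, sigmoidal rise in cases
    (midpoint at t = 5)."""
    t = np.asarray(t, dtype=float)
    if group == "control":
        return np.full_like(t, 30.0)
    return 40.0 * (1.0 / (1.0 + np.exp(-(t - 5.0))) + 0.25)


_TAXON_MEANS = {1: taxon1_mean, 2: taxon2_mean, 3: taxon3_mean}


def taxon_mean(taxon: int, t, group: str, variant: str = "literal"):
    if taxon == 2:
        return taxon2_mean(t, group, variant)
    return _TAXON_MEANS[taxon](t, group)


# ---------------------------------------------------------------------------
# Time grids and dataset assembly
# ---------------------------------------------------------------------------


def sample_time_grid(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-subject observation times, shape (n_subjects, n_timepoints).

    aligned: identical evenly spaced grids spanning the domain.
    misaligned: each subject draws one uniform time per equal subinterval
    (stratified), giving irregular schedules that still cover the domain.
    uniform: n_t sorted i.i.d. uniform draws per subject.
    """
    lo, hi = config.domain
    n = config.n_case + config.n_control
    n_t = config.n_timepoints
    if config.time_mode == "aligned":
        return np.tile(np.linspace(lo, hi, n_t), (n, 1))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.time_mode == "misaligned":
        edges = np.linspace(lo, hi, n_t + 1)
        u = rng.random((n, n_t))
        return edges[:-1] + u * np.diff(edges)
    times = np.sort(rng.random((n, n_t)), axis=1)
    return lo + times * (hi - lo)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[LongitudinalTable, dict[str, str]]:
    """Generate one synthetic dataset.

    Returns the longitudinal table (groups attached) and the subject → group
    map.  Deterministic given the config (one seeded generator drives taxon
    assignment, time grids, noise and sparsity, in that order).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    m = config.n_features
    n_t = config.n_timepoints
    lo, hi = config.domain

    subjects = [f"S{i + 1:03d}" for i in range(n)]
    groups = {
        s: ("case" if i < config.n_case else "control")
        for i, s in enumerate(subjects)
    }
    taxa = rng.choice([1, 2, 3], size=m, p=config.taxon_probs)
    times = sample_time_grid(config, rng)  # (n, n_t)

    sds = np.sqrt(np.asarray(config.noise_variances))
    sd_of_feature = sds[taxa - 1]  # (m,)

    # means: (n, n_t, m)
    means = np.empty((n, n_t, m))
    for taxon in (1, 2, 3):
        cols = np.flatnonzero(taxa == taxon)
        if cols.size == 0:
            continue
        for grp, rows in (
            ("case", np.arange(config.n_case)),
            ("control", np.arange(config.n_case, n)),
        ):
            mu = taxon_mean(taxon, times[rows], grp, config.taxon2_variant)
            means[np.ix_(rows, np.arange(n_t), cols)] = mu[:, :, None]

    noise = rng.standard_normal((n, n_t, m)) * sd_of_feature
    values = np.maximum(means + noise, 0.0)

    if config.sparsity > 0:
        flat = values.reshape(-1)
        n_zero = int(round(config.sparsity * flat.size))
        idx = rng.choice(flat.size, size=n_zero, replace=False)
        flat[idx] = 0.0
        values = flat.reshape(n, n_t, m)

    features = [f"F{j + 1:03d}" for j in range(m)]
    df = pd.DataFrame(
        {
            "subject": np.repeat(subjects, n_t * m),
            "time": np.repeat(times.reshape(-1), m),
            "feature": np.tile(features, n * n_t),
            "value": values.reshape(-1),
        }
    )
    table = LongitudinalTable.from_frame(df, T=hi, groups=groups)
    return table, groups


def apply_sparsity(
    table: LongitudinalTable, fraction: float, seed: int = 0
) -> LongitudinalTable:
    """Set exactly round(fraction * N) observation values to zero, chosen
    uniformly without replacement; keys are retained (zeros, not missing)."""
    if not (0.0 <= fraction < 1.0):
        raise ConfigurationError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return table
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n_zero = int(round(fraction * len(df)))
    idx = rng.choice(len(df), size=n_zero, replace=False)
    col = df.columns.get_loc("value")
    df.iloc[idx, col] = 0.0
    return replace(table, data=df)


# ---------------------------------------------------------------------------
# Replicate benchmark
# ---------------------------------------------------------------------------


def run_replicates(
    config: SimulationConfig,
    n_reps: int,
    pipeline_config: dict | None = None,
    n_perm: int = 999,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Simulate → distance → PERMANOVA, repeated.

    Replicate r uses seed ``config.seed + r`` for both data generation and
    the permutation test.  Returns a tidy frame (replicate, sparsity, F, p)
    and a summary dict with the fraction of non-significant replicates
    (p > 0.05) and the median F.
    """
    from .distance import lordist
    from .stats import permanova

    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    pipeline_config = dict(pipeline_config or {})
    pipeline_config.setdefault("keep_fpca", False)
    rows = []
    for r in range(1, n_reps + 1):
        seed_r = config.seed + r
        cfg = replace(config, seed=seed_r)
        table, groups = simulate_dataset(cfg)
        D, _, _ = lordist(table, **pipeline_config)
        res = permanova(D, groups, n_perm=n_perm, seed=seed_r)
        rows.append(
            {"replicate": r, "sparsity": config.sparsity, "F": res.F, "p": res.p}
        )
        if progress:
            print(f"  replicate {r}/{n_reps}: F={res.F:.3f} p={res.p:.4g}", flush=True)
    results = pd.DataFrame(rows)
    summary = {
        "n_reps": n_reps,
        "sparsity": config.sparsity,
        "frac_nonsignificant": float((results["p"] > 0.05).mean()),
        "median_F": float(results["F"].median()),
    }
    return results, summary
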