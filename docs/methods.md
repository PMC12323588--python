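# Methods

## The problem

Longitudinal microbiome studies observe each subject's microbial community
at a handful of time points that are often few, unevenly spaced, and
different from subject to subject, with many zero entries.  Most
beta-diversity tools compare *samples*; comparing *subjects* requires
integrating each feature's whole trajectory.  `lordist` treats each
subject-feature abundance series as a noisy sample from a smooth function
of time and compares subjects through the functional principal component
(FPC) representation of those functions.

## Model and procedure

For subject i and feature j, with observations x_ij(t_ijk) at times
t_ijk ∈ [0, T], the pipeline is:

1. **Smoothing.**  Each trajectory is represented as
   x̂_ij(t) = Σ_{l=1..K} c_ijl φ_l(t), with coefficients from penalized
   least squares: c = argmin ‖x − Φc‖² + λ c′Rc, where
   R_ab = ∫ φ_a⁽ᵖ⁾ φ_b⁽ᵖ⁾ dt is the order-p roughness penalty (p = 2 by
   default, penalizing curvature).  Bases: Fourier (constant plus sin/cos
   pairs at harmonics of 2π/T; K odd) or clamped uniform cubic B-splines.
2. **Per-feature FPCA.**  For each feature, the smoothed curves across
   subjects are decomposed as x̂_ij(t) ≈ μ_j(t) + Σ_{r=1..R} ξ_ijr ψ_jr(t),
   with orthonormal eigenfunctions ψ_jr, eigenvalues λ_jr (score
   variances) and subject scores ξ_ijr.
3. **Feature distance.**  d_j(S_i, S_i′) = (Σ_r λ_jr (ξ_ijr − ξ_i′jr)²)^{1/2} —
   the Euclidean distance between score vectors scaled by √λ_jr, so
   higher-variance components weigh more.
4. **Aggregation.**  D(S_i, S_i′) = (Σ_j d_j(S_i, S_i′)²)^{1/2}.  All
   features contribute equally (an optional user weight w_j on d_j² is
   available).  Because every subject embeds as the concatenation of its
   √λ-scaled score vectors, D is a Euclidean distance; principal-coordinate
   eigenvalues of D are non-negative up to rounding, which the test suite
   asserts.

Downstream, classical PCoA (double-centered Gower matrix, symmetric
eigendecomposition) visualizes the matrix, and one-way PERMANOVA
(pseudo-F with a seeded permutation null and the "+1" p-value rule
p = (1 + #{F* ≥ F}) / (1 + n_perm)) tests group separation.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `basis` | `fourier` | basis family; Fourier suits the periodic benchmark dynamics, B-splines suit aperiodic trends |
| `n_basis` (K) | `auto` = n_t | one basis function per observation time balances flexibility and overfitting; Fourier rounds an even n_t down to the nearest odd K (the family comes as 1 + sin/cos pairs); K is clamped to ≤ n_t so the λ = 0 system stays well posed |
| `lambda` (λ) | 1e-8 | near-interpolating but numerically stabilized; `"gcv"` selects λ per subject on a log grid 1e-8…1e2 by generalized cross-validation (not default, to keep runs deterministic and cheap) |
| `penalty_order` (p) | 2 | curvature penalty; as λ → ∞ the B-spline fit tends to the OLS line, the Fourier fit to the best constant |
| `grid_size` (G) | 101 | evaluation grid for FPCA; integrals use trapezoid quadrature on the grid (1001 points where a basis integral is needed), deterministic and ~1e-8 accurate for these smooth integrands |
| `components` (R) | `auto` | smallest R reaching 95% cumulative variance (min 1), per feature; a fixed integer is accepted — component choice is deliberately left to the user |
| PERMANOVA `n_perm` | 999 | permutation count; the attainable p floor is 1/(1+999) = 0.001 |

Time domain: all subjects share [0, T] with T = the dataset's maximum
observed time (the simulation fixes T = 10); the Fourier period equals T.

## Numerical choices

- FPCA is computed on the evaluation grid with quadrature weights
  (W^{1/2} C W^{1/2} symmetric eigenproblem) rather than in coefficient
  space; this supports mixed bases across subjects and is verifiable
  against closed forms.  Covariance uses the n − 1 denominator so λ equals
  the score variance.
- Eigenvalues in [−1e-10, 0) are clipped to 0; anything more negative
  raises an internal-consistency error.  Zero-variance features (e.g.
  all-zero after sparsification) produce a valid decomposition with λ = 0
  and contribute nothing to distances.
- Eigenfunction signs are fixed deterministically: flip so the quadrature
  integral is ≥ 0, ties broken on the first grid value.
- A subject lacking a feature at some of its sampled times is assigned
  value 0 there (not detected), keeping the subject set identical across
  features.
- The smoothing normal equations are solved by Cholesky factorization; at
  λ = 0 a rank-deficient design (duplicate times, or K exceeding the
  number of distinct times — note the periodic Fourier basis makes t = 0
  and t = T identical rows) raises an error advising λ > 0.
- With `n_basis="auto"` and a three-time-point subject, a cubic B-spline
  (order 4) would need K ≥ 4 > n_t; the spline order is reduced to K in
  that case so short series remain fittable with a quadratic spline.
- PERMANOVA permutations are uniform random relabelings from one seeded
  generator; F* ≥ F uses exact float comparison (ties have measure zero
  for continuous data).  An exhaustive mode enumerates all distinct
  two-group labelings for small designs and is cross-checked against the
  sampled mode in tests.  Degenerate designs with zero within-group sum of
  squares return F = +∞ with p still computed from permutations.
- PCoA reports negative eigenvalues rather than correcting them, since
  the package's distances are Euclidean by construction; Cailliez and
  Lingoes corrections are available for externally supplied matrices.

## The synthetic benchmark

The generator emulates a two-phenotype study: 100 subjects (50 cases, 50
controls), 10 time points on [0, 10], 200 features assigned uniformly to
three taxon archetypes, Gaussian noise with variances (3, 5, 9) matched to
each archetype's abundance scale, values clipped at 0:

- taxon 1: constant high abundance, x(t) = 10, identical in both groups —
  pure noise, no group signal;
- taxon 2: periodic intermediate abundance, control
  10(sin(πt + π/2) + 10); case 10(π/(1+e^(−t)) + 4·sin(πt + π/2) + 10).
  The case formula is implemented literally as printed; an
  `amplitude` variant, 10((π/(1+e^(−t)))·4·sin(πt + π/2) + 10), models the
  alternative reading in which the sigmoid modulates the oscillation
  amplitude;
- taxon 3: low abundance, control 30; case 40(1/(1+e^(−(t−5))) + 0.25), a
  sigmoidal rise with midpoint at t = 5.

Time grids are aligned (identical evenly spaced points) or misaligned
(each subject draws one uniform time per equal subinterval, so schedules
are irregular but cover the domain); a pure-uniform mode exists.  Sparsity
is injected by zeroing an exact fraction of the observed values, drawn
without replacement — zeros stay observations.  N(0, v) is read as
variance v.  Replicate r of a benchmark uses seed base + r for both
generation and permutation testing, making every run bit-reproducible.

What the generator does **not** emulate: sequencing-depth/compositional
count noise (values are Gaussian around smooth means, not multinomial
reads), overdispersion, phylogenetic correlation between features, and
subject-level random effects.  Passing benchmarks therefore demonstrate
the pipeline's statistical behavior under the stated functional model, not
performance on real sequencing data; the real-data preprocessing filters
are implemented and unit-tested separately.

## Problem sizes used in checks

The always-on suite runs the full-size design (100 subjects, 200
features) for the 20-replicate 50%-sparsity significance check and the
basis-configuration sweep, and 50 replicates per level for the
sparsity-ordering check; the standalone results script
(`scripts/acceptance.py`) uses 150 replicates per level for the 60%/70%
non-significance fractions.  These replicate counts are the package's
chosen benchmark sizes; sampling error at 150 replicates is reported
alongside the fractions.

## Known limitations

- At least three time points per subject are required; subjects below the
  threshold are dropped (with a report), not imputed.
- With near-interpolating λ and very sparse series, fitted curves can
  oscillate between observations; heavier smoothing (or `"gcv"`) trades
  bias for stability.
- The default pipeline retains substantially more statistical power under
  heavy injected sparsity than some published longitudinal benchmarks
  report for comparable designs; power at 60–70% sparsity is sensitive to
  smoothing and component-selection choices that such reports often leave
  unstated.  The benchmark here reports what this implementation computes.
- Feature weighting beyond the optional user vector (e.g. phylogenetic
  similarity) is out of scope.
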