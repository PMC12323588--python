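"""Per-feature functional PCA: eigenvalues, variance explained, scores.

Builds 12 subject trajectories of one feature whose group difference is a
sigmoidal rise (the low-abundance archetype of the benchmark), smooths them
and decomposes the curves.  The leading component captures the rise, and
the subject scores on it separate the groups.
"""

import numpy as np

from lordist import BasisSystem, fit_fpca, smooth_trajectory, taxon3_mean, variance_explained

rng = np.random.default_rng(2)
T, times = 10.0, np.linspace(0, 10, 8)
basis = BasisSystem.create("fourier", 7, T)

curves = []
groups = []
for i in range(12):
    group = "case" if i < 6 else "control"
    y = taxon3_mean(times, group) + rng.normal(0, 3.0, size=times.size)
    curves.append(
        smooth_trajectory(times, y, basis, 1e-8, subject_id=f"S{i:02d}")
    )
    groups.append(group)

fp = fit_fpca(curves, R="auto")
ve = variance_explained(fp)
print(f"retained components: {fp.n_components}")
print("eigenvalues:        ", "  ".join(f"{v:8.1f}" for v in fp.eigenvalues))
print("variance explained: ", "  ".join(f"{v:8.1%}" for v in ve))
pc1 = fp.scores[:, 0]
print(f"mean PC1 score, cases:    {pc1[:6].mean():8.1f}")
print(f"mean PC1 score, controls: {pc1[6:].mean():8.1f}")
print("-> one component explains most temporal variance and its scores "
      "split cases (rising curves) from controls (flat curves).")
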