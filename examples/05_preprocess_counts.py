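"""Preprocessing a count table the way a real study would be prepared.

Builds a small OTU-style count table, then applies the standard chain:
minimum-total-count feature filter -> total-sum scaling -> prevalence/
abundance filter -> at-least-three-time-points subject rule.
"""

import numpy as np
import pandas as pd

from lordist import (
    LongitudinalTable,
    filter_low_abundance_features,
    filter_low_count_features,
    require_min_timepoints,
    tss_normalize,
)

rng = np.random.default_rng(5)
rows = []
for s, n_t in (("S1", 5), ("S2", 4), ("S3", 2)):  # S3 has too few time points
    for t in range(n_t):
        for j in range(10):  # abundant community members
            rows.append([s, float(t), f"OTU{j:02d}", float(rng.poisson(2000))])
        # OTU10: 1 count in every sample -> total >= 5 but relative ~5e-5,
        # below the 0.01% abundance threshold in every sample
        rows.append([s, float(t), "OTU10", 1.0])
        # OTU11: a single count in one sample -> total below 5
        rows.append([s, float(t), "OTU11", 1.0 if (s, t) == ("S1", 0) else 0.0])
table = LongitudinalTable.from_frame(
    pd.DataFrame(rows, columns=["subject", "time", "feature", "value"])
)
print(f"raw:                 {len(table.features):3d} features, "
      f"{len(table.subjects)} subjects")

step1 = filter_low_count_features(table, min_total=5)
print(f"count filter (>=5):  {len(step1.features):3d} features "
      f"(removed: {', '.join(sorted(set(table.features) - set(step1.features)))})")

rel = tss_normalize(step1)
step2 = filter_low_abundance_features(rel, min_rel=1e-4, max_frac=0.9)
print(f"prevalence filter:   {len(step2.features):3d} features "
      f"(removed: {', '.join(sorted(set(step1.features) - set(step2.features)))})")

step3 = require_min_timepoints(step2, min_k=3)
print(f"min 3 time points:   {len(step3.subjects)} subjects "
      f"(dropped: {', '.join(step3.dropped_subjects)})")
sums = rel.data.groupby(["subject", "time"])["value"].sum()
print(f"per-sample totals after TSS: all within {abs(sums - 1).max():.1e} of 1 "
      "(later filters remove the dropped features' tiny shares)")
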