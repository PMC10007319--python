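"""Reproducibility metrics over replicate scans.

Four replicates of one array share geometry and amplitudes but carry
independent noise; per-spot mean absolute error (MAE) of the replicate
intensities and the per-spot coefficient of variation (CV) quantify how
reproducible the segmentation is.
"""

import numpy as np

from hexspot import SyntheticConfig, replicate_metrics, replicate_set, run_pipeline

cfg = SyntheticConfig(seed=10, missing_fraction=0.0, weak_fraction=0.0)
replicates = replicate_set(cfg, r=4)

tables = []
for image, _ in replicates:
    spots = run_pipeline(image).spots.sort_values(["line", "col"])
    tables.append(spots.intensity.to_numpy())
intensities = np.column_stack(tables)  # spots x replicates

mae, avg_mae = replicate_metrics(intensities)
cv = run_pipeline(replicates[0][0]).spots.cv
print(f"{intensities.shape[0]} spots x {intensities.shape[1]} replicates")
print(f"average replicate MAE : {avg_mae:.0f} counts "
      f"(small against the 1..65536 dynamic range = reproducible)")
print(f"median per-spot CV    : {np.nanmedian(cv):.3f} "
      "(std/mean of background-subtracted foreground; low = homogeneous spots)")
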