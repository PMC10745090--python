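"""Recovering planted semantic voxels with a nested-CV ridge encoder.

Generates a small synthetic cohort, fits the baseline and the
baseline+semantic encoding models, and compares cross-validated ΔR at
planted semantic voxels against null voxels, with group-level FDR masks.
"""

import numpy as np

from semsyn.simulate import SimConfig, generate_dataset
from semsyn.workflows import encode_cohort

cfg = SimConfig(
    n_runs=5, tokens_per_run=120, n_subjects=6,
    class_counts={"semantic": 12, "syntactic": 12, "mixed": 12,
                  "interaction": 12, "context5": 6, "context15": 6,
                  "null": 60},
    grid_shape=(6, 5, 6), gap_layers=(2, 3), seed=7,
)
ds = generate_dataset(cfg)
res = encode_cohort(ds, models={"semantic": ("sem",)})

m = ds.manifest
dr = res.delta["semantic"].mean(axis=0)           # group-mean ΔR per voxel
sem, null = m.voxels_of("semantic"), m.voxels_of("null")
g = res.group["semantic"]

print(f"mean ΔR at planted semantic voxels: {dr[sem].mean():.3f}")
print(f"mean ΔR at null voxels:             {dr[null].mean():+.3f}")
print(f"group FDR(q=0.005) sensitivity:     {g.mask[sem].mean():.2f}"
      f"   false-positive rate: {g.mask[null].mean():.3f}")
print(f"z_FDR threshold: {g.z_fdr:.2f}")
print("ΔR is the gain in cross-validated correlation over the confound-only")
print("baseline; planted voxels should gain, null voxels should not.")
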