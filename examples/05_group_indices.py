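"""Semantic/syntactic comparison indices on a small synthetic cohort.

Computes the specificity index, per-hemisphere peak-region Jaccard overlap
and hemisphere counts from semantic and syntactic encoding models.
"""

import numpy as np

from semsyn.grids import VoxelGrid, VoxelMap
from semsyn.group import (hemisphere_counts, jaccard, peak_regions,
                          specificity_index)
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
res = encode_cohort(ds, models={"semantic": ("sem",), "syntactic": ("syn",)})

dr_sem = res.delta["semantic"].mean(axis=0)
dr_syn = res.delta["syntactic"].mean(axis=0)
sp = specificity_index(VoxelMap(dr_sem, ds.grid), VoxelMap(dr_syn, ds.grid))
m = ds.manifest
sem_x = sp.values[m.voxels_of("semantic")]
syn_x = sp.values[m.voxels_of("syntactic")]
print(f"specificity x = log10(ΔR_sem/ΔR_syn), defined at {sp.valid.sum()} voxels")
print(f"  planted semantic voxels:  median x = {np.nanmedian(sem_x):+.2f} (expect > 0)")
print(f"  planted syntactic voxels: median x = {np.nanmedian(syn_x):+.2f} (expect < 0)")

for hemi in ("L", "R"):
    sel = np.flatnonzero(ds.grid.hemisphere == hemi)
    sub = VoxelGrid(coords=ds.grid.coords[sel], hemisphere=ds.grid.hemisphere[sel],
                    voxel_ids=ds.grid.voxel_ids[sel])
    a = peak_regions(VoxelMap(dr_sem[sel], sub))
    b = peak_regions(VoxelMap(dr_syn[sel], sub))
    print(f"hemisphere {hemi}: peak-region Jaccard(sem, syn) = {jaccard(a, b):.2f}")

counts = hemisphere_counts(res.group["semantic"].mask, ds.grid)
print(f"significant semantic voxels: {counts['left']} left, {counts['right']} right")
print("the left hemisphere carries disjoint semantic/syntactic blocks, the")
print("right an overlapping mixed block, so the Jaccard overlap differs by design")
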