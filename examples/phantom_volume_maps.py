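"""Simulate a noisy phantom volume and map delta_omega / B1 voxelwise.

Builds the default synthetic head phantom (smooth truth fields on an
ellipsoid, sigma = 0.02 noise, two motion-artifact patches), runs the
volume fitter, and grades the result against the known truth with the
0.15 ppm ill-estimated-voxel rule.
"""

import numpy as np

from radish import fit_volume, make_default_phantom, quantify_artifacts, bland_altman

truth, wasabi_4d, m0, offsets, ctx, spec = make_default_phantom(seed=1)
print(f"phantom {spec.shape}, {int(truth.mask.sum())} voxels in mask, "
      f"noise sigma {spec.noise_sigma}")

maps = fit_volume(wasabi_4d, m0, offsets, ctx, mask=truth.mask)
print(f"valid voxels: {int(maps.valid_mask.sum())}, failures: {maps.failure_counts}")

_, pct = quantify_artifacts(maps.delta_omega_map, truth.delta_omega_map, truth.mask)
stats = bland_altman(maps.delta_omega_map, truth.delta_omega_map, truth.mask)
print(f"ill-estimated voxels (>0.15 ppm from truth): {pct:.2f}%")
print(f"delta_omega bias vs truth: {stats.bias*1000:.2f} mppm, "
      f"LoA [{stats.loa_lower:.4f}, {stats.loa_upper:.4f}] ppm")

rb1_err = (maps.rb1_map - truth.rb1_map)[maps.valid_mask]
print(f"relative-B1 mean abs error: {np.nanmean(np.abs(rb1_err)):.4f}")
# Artifact percentage near zero means the maps track the simulated field
# inhomogeneities; the limits of agreement show the voxelwise noise floor.
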