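"""Apply a fitted water-shift map to correct CEST spectra.

Builds CEST-like Z-spectra with a direct-saturation dip displaced by a
known per-voxel water shift, corrects them by axis-shifting linear
interpolation, and checks the dip returns to 0 ppm.  Also shows the
two-point B1 contrast correction on a synthetic linear contrast.
"""

import numpy as np

from radish import correct_cest_b0, correct_cest_b1_two_point

offsets = np.linspace(-4.0, 4.0, 81)
shape = (4, 4, 1)
rng = np.random.default_rng(0)
dw_map = rng.uniform(-0.4, 0.4, shape)

cest = np.empty(shape + (offsets.size,))
for idx in np.ndindex(shape):
    cest[idx] = 1.0 - 0.8 / (((offsets - dw_map[idx]) ** 2) + 0.4)

corrected = correct_cest_b0(cest, offsets, dw_map)
centres_before = [offsets[np.nanargmin(cest[idx])] for idx in np.ndindex(shape)]
centres_after = [offsets[np.nanargmin(corrected[idx])] for idx in np.ndindex(shape)]
print(f"water dip position, mean |offset| before: {np.mean(np.abs(centres_before)):.3f} ppm")
print(f"water dip position, mean |offset| after : {np.mean(np.abs(centres_after)):.3f} ppm")

# two-point B1 correction: contrast proportional to actual local B1
rb1 = rng.uniform(0.5, 1.2, shape)
levels = (0.6, 1.2)  # nominal saturation amplitudes of the two acquisitions, uT
contrast_a = 0.05 * rb1 * levels[0]
contrast_b = 0.05 * rb1 * levels[1]
fixed = correct_cest_b1_two_point(contrast_a, contrast_b, levels, rb1)
print(f"B1-corrected contrast spread before: {contrast_a.std():.5f}")
print(f"B1-corrected contrast spread after : {fixed.std():.5f} "
      f"(target value {0.05 * levels[0]:.3f})")
# After correction every voxel reports the contrast it would have shown at
# the nominal B1, removing the transmit-field shading.
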