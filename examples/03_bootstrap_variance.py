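"""Bootstrap 3-D variance mapping with background subtraction.

Mixes projections from two particle conformations (with and without one
strong surface domain), reconstructs 200 bootstrap volumes, subtracts the
variance measured on background-only images, and reports how well the
top-variance voxels localize the known differing region.
"""

import numpy as np

from lipovol.core import ImageStack, VolumeMap
from lipovol.geometry import project, uniform_orientations
from lipovol.heterogeneity import bootstrap_variance
from lipovol.phantom import default_phantom_spec, make_phantom

n, vox = 32, 10.0
base = make_phantom(default_phantom_spec("disordered", box_size=n,
                                         voxel_size=vox, knob=False))
c = (n - 1) / 2
zz, yy, xx = np.mgrid[:n, :n, :n]
r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * vox
patch = (r > 90) & (r < 115) & ((xx - c) * vox / np.maximum(r, 1e-9) > 0.85)
variant = VolumeMap(base.data + 3.0 * patch, vox)
print(f"differing region: {patch.sum()} voxels "
      f"({100 * patch.sum() / patch.size:.1f}% of the box)")

rng = np.random.default_rng(0)
angles = uniform_orientations(200, rng)
images = np.stack([
    project(variant if i % 2 == 0 else base, a) + rng.normal(0, 2.0, (n, n))
    for i, a in enumerate(angles)])
background = ImageStack(rng.normal(0, 2.0, (200, n, n)).astype(np.float32), vox)

result = bootstrap_variance(ImageStack(images, vox), angles, n_bootstrap=200,
                            background_stack=background, seed=0)

cv = result.corrected_variance_map.data
k = max(1, int(0.01 * cv.size))
top = cv >= np.partition(cv.ravel(), -k)[-k]
dice = 2 * (top & patch).sum() / (top.sum() + patch.sum())
print(f"raw variance 99th pct: {np.percentile(result.raw_variance_map.data, 99):.4f}")
print(f"background variance 99th pct: "
      f"{np.percentile(result.background_variance_map.data, 99):.4f}")
print(f"Dice overlap of top-1% corrected-variance voxels with the known "
      f"differing region: {dice:.2f}")
# Dice >= 0.3 means the variance map localizes the conformational difference
# rather than reconstruction or noise artifacts
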