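"""Recover a known synthetic deformation and measure the endpoint error.

Builds a 32^3 phantom pair whose source is the target deformed by a known
smooth field (max 2 voxels), registers source onto target, and compares the
recovered displacement field with the ground truth.
"""

import numpy as np

from gcdeform import PhantomSpec, RegistrationConfig, make_registration_pair, register

spec = PhantomSpec(
    shape=(32, 32, 32), n_blobs=4, blob_sigma_range=(4.0, 6.0),
    warp_amplitude=2.0, warp_sigma=7.0, seed=42,
)
target, source, truth, target_labels, _ = make_registration_pair(spec)

cfg = RegistrationConfig(n_levels=2, block_size=8)
u, reports = register(target, source, cfg)

fg = target_labels.data > 0
epe = np.linalg.norm(u.vectors - truth.vectors, axis=-1)
print(f"sweeps run:                 {len(reports)}")
print(f"final energy:               {reports[-1].energy_after:.2f}")
print(f"mean endpoint error (fg):   {epe[fg].mean():.3f} voxels")
print(f"max true displacement:      {np.linalg.norm(truth.vectors, axis=-1).max():.2f} voxels")

# The endpoint error is the per-voxel distance between recovered and true
# displacement; well below 1 voxel on the foreground means the registration
# found the deformation to sub-voxel accuracy (the move step is 0.5 voxels).
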