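"""Atlas-style label propagation: warp source labels and score Dice overlap.

Registers a synthetic pair, transfers the source segmentation to the target
grid through the recovered field (nearest-neighbor, labels are categorical),
and prints the per-region Dice overlap against the true target labels.
"""

import numpy as np

from gcdeform import (
    PhantomSpec,
    RegistrationConfig,
    dice_per_region,
    make_registration_pair,
    register,
    warp_labels,
)

spec = PhantomSpec(shape=(32, 32, 32), n_blobs=4, blob_sigma_range=(4.0, 6.0),
                   warp_amplitude=2.0, warp_sigma=7.0, seed=7)
target, source, truth, target_labels, source_labels = make_registration_pair(spec)

u, _ = register(target, source, RegistrationConfig(n_levels=2, block_size=8))

before = dice_per_region(target_labels, source_labels)
after = dice_per_region(target_labels, warp_labels(source_labels, u))
print("region   dice before   dice after")
for region in sorted(after):
    print(f"{region:6d}   {before[region]:.3f}         {after[region]:.3f}")
print(f"mean     {np.mean(list(before.values())):.3f}         "
      f"{np.mean(list(after.values())):.3f}")

# Dice of 1.0 is perfect overlap; registration should lift every region well
# above its unregistered overlap. Residual misses concentrate on region
# borders, where label rounding costs a voxel-thin shell.
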