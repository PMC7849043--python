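# gcdeform

Dense deformable 3-D image registration by blockwise graph-cut move-making —
for volumetric (e.g., medical MRI/CT) image analysis where a per-voxel
displacement field is needed: atlas-based label propagation, longitudinal
comparison, morphometry.

## Method

Given a fixed target volume `T` and a moving source volume `S`, gcdeform
estimates a dense displacement field `u` (one 3-vector per voxel, pull-back
convention `W(x) = x + u(x)`) minimizing

```
f(u) = Σ_v ½(1 − PCC(T|ω(v,r), Ŝ|ω(v,r)))  +  α Σ_(v,w)∈N ‖u(v) − u(w)‖^γ
```

a windowed Pearson-correlation data term over small spherical windows plus a
diffusion regularizer over 6-neighbor pairs. Optimization is discrete
move-making: each move offers every voxel in a subregion a binary choice —
keep its displacement or add a fixed sub-voxel step `δ = ±ε e_i` — and the
optimal choice set is found *exactly* as a minimum s-t graph cut (the move
energies are provably submodular for `γ ≥ 2`). Sweeping the six signed axis
steps over all blocks inside a coarse-to-fine pyramid monotonically drives
the energy down until no improving move remains. Block processing is
checkerboard-scheduled, so multi-worker runs reproduce serial results
exactly. Quality metrics (Jacobian determinant / folding count, per-region
Dice after label propagation) and a synthetic phantom generator with known
ground-truth deformations are included.

See `docs/methods.md` for assumptions, parameter semantics and limitations.

## Worked example

`examples/01_recover_known_deformation.py` builds a 32³ phantom pair whose
source is the target deformed by a known smooth field (2-voxel maximum
displacement), registers it, and compares against the truth:

```
$ python examples/01_recover_known_deformation.py
sweeps run:                 38
final energy:               265.27
mean endpoint error (fg):   0.486 voxels
max true displacement:      2.00 voxels
```

The recovered field agrees with the ground truth to under half a voxel on
the labeled foreground — sub-voxel accuracy from the 0.5-voxel move step and
its half-step refinement stage. The other examples cover label propagation with Dice
scoring, fold checking via the Jacobian determinant, and the equivalent
shell pipeline through the CLI:

```sh
gcdeform synth --out-dir pair/ --shape 48 48 48 --seed 1
gcdeform register --fixed pair/target.nii.gz --moving pair/source.nii.gz \
    --out field.nii.gz --manifest run.json
gcdeform transform --input pair/source_labels.nii.gz --field field.nii.gz \
    --out propagated.nii.gz --labels
gcdeform dice --a pair/target_labels.nii.gz --b propagated.nii.gz
gcdeform jacobian --field field.nii.gz
```

All volumes are NIfTI-1 (`.nii`/`.nii.gz`); displacement fields are NIfTI
with a trailing vector dimension of size 3, in voxel units.

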