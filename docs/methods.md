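# Methods

## Model

gcdeform estimates a dense displacement field `u` mapping the voxel grid of a
target (fixed) volume `T` into a source (moving) volume `S`, under the
pull-back convention `W(x) = x + u(x)`: the registered source is `S(W(x))`.
The field minimizes

```
f(u) = D(u) + α R(u)
```

- **Data term** `D(u) = Σ_v ½ (1 − PCC(T|ω(v,r), Ŝ|ω(v,r)))`, where
  `ω(v, r)` is the spherical window of radius `r` voxels around `v`
  (truncated at image borders) and `Ŝ` is the source sampled at
  `w + u(v)` for every window point `w` — the window is assumed rigid with
  respect to its center voxel. PCC is Pearson's correlation; the term lies in
  [0, 1], with 0 for perfect positive correlation. Flat (zero-variance)
  patches carry no linear-correlation evidence and are assigned PCC = 0
  (data term ½). Negative correlations are penalized (term above ½); no
  absolute-value matching is attempted, so the metric is single-modality.
  A pointwise SSD metric is available as an alternative (`metric="ssd"`).
- **Regularizer** `R(u) = Σ_(v,w)∈N ‖u(v) − u(w)‖^γ` over 6-neighbor pairs
  (a diffusion penalty). `γ ≥ 2` is enforced: it is the range in which the
  move energies below are provably submodular.

## Optimization

The field is improved by **binary moves**: given a step `δ = ±ε e_i` along a
coordinate axis, every voxel either keeps its displacement or adds `δ`
(`u'(x) = u(x) + L(x) δ`, `L(x) ∈ {0,1}`). Restricted to a block `V'` of the
grid, the move energy decomposes into unary tables (the data term at both
labels) and pairwise tables

```
ϕ_vw(L(v), L(w)) = α ‖(u(v) + L(v)δ) − (u(w) + L(w)δ)‖^γ
```

for in-block neighbor pairs; pairs crossing the block boundary freeze the
outside endpoint at label 0 and act as unary addends on the inside endpoint.
Every pairwise table satisfies `ϕ(0,0) + ϕ(1,1) ≤ ϕ(0,1) + ϕ(1,0)` for any
`u`, `δ` and `γ ≥ 2` (for `γ = 2` by direct expansion; for `γ > 2` because
additionally `max{ϕ(0,0), ϕ(1,1)} ≤ max{ϕ(1,0), ϕ(0,1)}`, which licenses
raising a submodular quadratic to any power ≥ 1). The optimal labeling is
therefore an exact s-t minimum cut. A runtime guard rejects non-submodular
tables rather than returning a wrong cut.

A **sweep** tries all six signed axis steps over all blocks; sweeps repeat
until one accepts no flips, or a per-level cap is reached, inside a
coarse-to-fine Gaussian pyramid (smoothing σ = 1 voxel, decimation by 2;
displacement fields are stored in voxel units of their level and are
upsampled by trilinear interpolation with vectors scaled by the shape ratio).
Moves are accepted only when they strictly lower the block energy (ties
within 1e-9 keep the null move, guaranteeing termination), so the global
energy is non-increasing by construction.

Design choices on points the method description leaves open:

- **Both signs of each axis step** are proposed. With only `+ε e_i` moves no
  positive displacement component could ever decrease, and "no improving
  move exists" would be unreachable.
- **Block offsets alternate** between 0 and `block_size/2` per sweep, so
  block boundaries — where the subregion restriction slightly biases the
  solution — do not stay in one place.
- **α placement**: α multiplies every pairwise term; unary (data) terms are
  unweighted.
- **Out-of-bounds sampling** replicates the border voxel. Clamping avoids
  injecting artificial gradients at boundaries.
- **Checkerboard scheduling**: blocks are colored by the parity of their
  block-grid index sum; 6-adjacent blocks always differ in color, so blocks
  of one color share no pairwise term and can be solved in any order or
  concurrently. Colors are processed sequentially. The final field is
  identical for every worker count, making the worker pool an execution
  contract rather than a numerical trade-off.
- **Subiteration scope**: one signed step δ per block pass (six passes per
  sweep).

## Min-cut backend

The blockwise binary problems are reduced to max-flow with the standard
construction (each submodular pairwise table becomes one non-negative arc
plus unary adjustments; label 1 = source side of the cut). The max flow is
computed by a Dinic solver compiled with numba operating directly on float64
capacities. This keeps the cut exact in floating point — no capacity
quantization — which the oracle-equivalence tests rely on. Augmentation
terminates because each augmenting path zeroes its bottleneck arc exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.25 | regularization weight on the pairwise terms |
| `gamma` | 4.0 | regularizer exponent (≥ 2 required for submodularity). γ=4 leaves smooth sub-voxel displacement gradients essentially unpenalized while pricing folding-scale jumps steeply — in validation it recovers deformations markedly better than γ=2 at the same α, with zero folded voxels |
| `epsilon` | 0.5 voxel | move step; the displacement search grid |
| `epsilon_refinements` | 1 | step halvings appended after convergence at each level: sweeps continue at ε/2 (then ε/4, ...), refining the ε-grid quantization while the full-size steps retain their ability to escape local minima |
| `radius` | 3 voxels | PCC window radius (123-point spherical window). The correlation of a K-sample window has a noise floor ~1/√K; the larger window halves noise-driven displacement drift relative to radius 2, at a stronger rigid-window approximation |
| `presmooth_sigma` | 1.5 voxels | Gaussian smoothing of both inputs before registration; suppresses the data term's incentive to chase uncorrelated acquisition noise while leaving structure a few voxels wide intact |
| `block_size` | 16 | subregion edge length |
| `n_levels` | 3 | pyramid depth |
| `max_sweeps_per_level` | 50 | safety cap per refinement stage; stages normally stop at zero flips |

Defaults are conventions of this implementation, selected by diagnosing
failure modes on the synthetic validation pairs described below (noise-driven
drift, regularizer-induced shrinkage, capture range) rather than prescribed
by the underlying method; real data will generally need problem-specific
values (`alpha`, `epsilon` and `presmooth_sigma` foremost). Voxel spacing is
carried as metadata only; displacements are computed in voxel units, so
anisotropic spacing changes the physical meaning of the regularizer but not
the arithmetic.

## Synthetic study conditions

The fixture generator produces 48³ phantoms with two blob populations,
mimicking segmentable anatomy with internal texture:

- 12 large **region blobs** (σ between 4 and 6.5 voxels, distinct peaks,
  centers rejection-sampled with a minimum separation) carry the labels:
  each blob's ~2σ ball, truncated where a brighter neighbor dominates. The
  separation keeps every region above ~600 voxels, large enough that
  per-region Dice is limited by alignment rather than by single-voxel label
  rounding (propagating labels through the exact ground-truth field scores
  0.93–0.95 for the worst region).
- 40 small signed **texture blobs** (σ between 1.5 and 3 voxels, unlabeled)
  provide fine-scale intensity structure. This matters because PCC is
  invariant to affine intensity maps: patches of large smooth blobs are
  locally near-affine and carry almost no matching signal, so without
  texture the data term cannot see the deformation at all.

Ground-truth warps are Gaussian-smoothed random vector fields (smoothing
σ = 8 voxels, zero-padded so the field decays at volume borders and its
maximum is an interior bump, not a border artifact) rescaled to a 3-voxel
maximum displacement and verified fold-free.

The phantom is an analytic Gaussian sum, so the deformed view is evaluated
exactly at `x + truth(x)`: the source is the base phantom, the target its
exactly warped view, and no resampling blur enters the pair (resampling the
source through an inverted field was found to blur it in proportion to local
warp magnitude, biasing the matching optimum toward shrunken fields).
I.i.d. Gaussian noise at 2% of the dynamic range is added to target and
source independently (scan/rescan noise, not interpolated noise). All
outputs are deterministic functions of the spec, seed included.

These phantoms emulate single-modality contrast with organ-scale regions,
sub-organ texture and moderate smooth deformation. They do **not** contain
thin folded structures, bias fields, occlusion, or intensity nonlinearities
between the two volumes — passing the recovery tests shows the optimizer
and metrics are correct on well-posed input, not that the default
parameters are optimal for any particular imaging domain.

## Numerical notes

- All arithmetic is float64; energies are accumulated in float64.
- The windowed-PCC data term is computed by a single compiled kernel (window
  gather, trilinear source sampling, one-pass correlation sums). The sweep
  loop evaluates it for the whole volume per candidate step and maintains
  the label-0 table incrementally; because every code path runs the same
  kernel, sweeps' reported energies equal an independent recomputation
  bitwise.
- Windows whose variance is below 1e-12 of their raw second moment are
  treated as flat: PCC 0, data term ½.
- The Jacobian uses central differences in the interior and one-sided
  differences at faces; boundary voxels are included in folding counts by
  default (configurable to interior-only).
- Dice for regions absent from both volumes is NaN (undefined), never 0 or
  1, and is excluded from mean aggregation.

## Problem sizes

Tests and the acceptance script run registrations at 48³ (recovery,
monotonicity, parallel determinism; three pyramid levels) and 32³ (identity
fixed point), with smaller grids for unit-level checks. These sizes keep a
full test cycle short while leaving every code path — pyramid, block
tiling with remainders, boundary terms, both checkerboard colors —
exercised.

## Known limitations

- No affine pre-registration: initialization is the identity transform or a
  user-supplied field. Pairs with large global misalignment need external
  initialization.
- Displacements live on the ε-grid; accuracy below ε/2 per axis is not
  attainable without lowering ε.
- The method does not guarantee diffeomorphic fields; the diffusion
  regularizer merely makes folding rare (measured, not enforced).
- Single-modality metric only; no mutual information.
- A paired statistical comparison of two methods' per-region Dice tables
  (e.g., a two-sided paired t-test over regions) is a one-line downstream
  step with `scipy.stats.ttest_rel`; it is documented here rather than
  wrapped in the API.
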