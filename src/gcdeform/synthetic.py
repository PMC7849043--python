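"""Synthetic fixtures: blob phantoms, smooth fold-free warps, paired volumes.

Every stage of the pipeline can be exercised without external data. A phantom
is a sum of Gaussian blobs with distinct peak intensities plus i.i.d. Gaussian
noise; its label volume assigns each voxel near a blob to that blob's region.
Ground-truth warps are Gaussian-smoothed random vector fields rescaled to a
prescribed maximum displacement and verified to be orientation-preserving
(zero folding). Registration pairs follow the pull-back convention of the
optimizer: the source volume is constructed so that sampling it at x +
truth(x) reconstructs the (noise-free) target.

What this emulates — and what it does not — is discussed in docs/methods.md:
smooth single-modality contrast with scan/rescan noise, no anatomy, no bias
fields, no intensity nonlinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import DisplacementField, Volume, warp_volume
from .evaluation import LabelVolume, count_foldings, jacobian_determinant, warp_labels

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_ground_truth_warp",
    "make_registration_pair",
    "invert_field",
]


@dataclass
class PhantomSpec:
    """Generator parameters for one phantom / registration pair.

    Two blob populations mimic anatomy: ``n_blobs`` large region blobs carry
    the labels (segmentable structures), while ``n_texture_blobs`` smaller,
    signed, unlabeled blobs add internal intensity texture — structure the
    windowed correlation metric can latch onto at fine scales, the way real
    tissue has sub-organ detail. noise_sigma is the noise standard deviation
    expressed as a fraction of the clean phantom's dynamic range (0.02 = 2%
    noise). warp_amplitude is the maximum displacement norm of the
    ground-truth warp in voxels; warp_sigma its smoothing scale in voxels.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_blobs: int = 12
    blob_sigma_range: tuple[float, float] = (4.0, 6.5)
    n_texture_blobs: int = 40
    texture_sigma_range: tuple[float, float] = (1.5, 3.0)
    texture_amplitude: float = 30.0
    noise_sigma: float = 0.02
    warp_amplitude: float = 3.0
    warp_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        lo, hi = self.blob_sigma_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid blob_sigma_range {self.blob_sigma_range}")
        if self.noise_sigma < 0 or self.warp_amplitude < 0 or self.warp_sigma <= 0:
            raise ValueError("noise_sigma/warp_amplitude must be >= 0, warp_sigma > 0")


def _blob_params(spec: PhantomSpec, rng: np.random.Generator):
    """Region-blob and texture-blob parameters drawn from one generator."""
    shape = np.array(spec.shape)
    lo = spec.blob_sigma_range[0]
    if np.any(shape < 2 * lo):
        raise ValueError(
            f"shape {spec.shape} too small to place blobs of sigma >= {lo}"
        )
    margin = 0.2 * shape
    # rejection-sample region-blob centers with a minimum separation so no
    # region is truncated to a sliver by a closer, brighter neighbor
    min_sep = 1.6 * spec.blob_sigma_range[0]
    centers = np.empty((spec.n_blobs, 3))
    placed = 0
    for _ in range(10000):
        cand = rng.uniform(margin, shape - margin)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - cand, axis=1)
        ) >= min_sep:
            centers[placed] = cand
            placed += 1
            if placed == spec.n_blobs:
                break
    if placed < spec.n_blobs:
        raise ValueError(
            f"could not place {spec.n_blobs} separated blobs in shape {spec.shape}"
        )
    sigmas = rng.uniform(*spec.blob_sigma_range, size=spec.n_blobs)
    # distinct peaks so regions are identifiable from intensity alone
    peaks = 100.0 * (0.6 + 0.4 * np.arange(spec.n_blobs) / max(spec.n_blobs - 1, 1))
    peaks = rng.permutation(peaks)
    # texture blobs: smaller, signed, spread over the whole volume
    nt = spec.n_texture_blobs
    t_centers = rng.uniform(0, shape, size=(nt, 3))
    t_sigmas = rng.uniform(*spec.texture_sigma_range, size=nt)
    t_amps = spec.texture_amplitude * rng.choice([-1.0, 1.0], nt) * rng.uniform(0.5, 1.0, nt)
    return centers, sigmas, peaks, t_centers, t_sigmas, t_amps


def _eval_phantom(points: np.ndarray, params):
    """Analytic phantom intensity and label at arbitrary continuous points.

    Intensity sums the region blobs, the signed texture blobs and nothing
    else; a point is labeled with its dominant region blob if that blob
    contributes at least exp(-2) of its peak (roughly the 2-sigma ball),
    else background — texture blobs never carry labels. Being closed-form,
    the phantom can be evaluated exactly on deformed coordinates, so no
    resampling blur enters generated image pairs.
    """
    centers, sigmas, peaks, t_centers, t_sigmas, t_amps = params
    intensity = np.zeros(len(points))
    best = np.full(len(points), -np.inf)
    winner = np.zeros(len(points), dtype=np.int32)
    winner_peak = np.ones(len(points))
    for i, (c, s, p) in enumerate(zip(centers, sigmas, peaks)):
        d2 = ((points - c) ** 2).sum(axis=1)
        f = p * np.exp(-d2 / (2.0 * s * s))
        intensity += f
        better = f > best
        best = np.where(better, f, best)
        winner = np.where(better, i + 1, winner)
        winner_peak = np.where(better, p, winner_peak)
    labels = np.where(best >= winner_peak * np.exp(-2.0), winner, 0).astype(np.int32)
    for c, s, a in zip(t_centers, t_sigmas, t_amps):
        d2 = ((points - c) ** 2).sum(axis=1)
        intensity += a * np.exp(-d2 / (2.0 * s * s))
    return intensity, labels


def _grid_points(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)


def _phantom_clean(spec: PhantomSpec, rng: np.random.Generator):
    params = _blob_params(spec, rng)
    intensity, labels = _eval_phantom(_grid_points(spec.shape), params)
    return intensity.reshape(spec.shape), labels.reshape(spec.shape)


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Blob phantom plus matching label volume; deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    clean, labels = _phantom_clean(spec, rng)
    dyn = clean.max() - clean.min()
    noisy = clean + spec.noise_sigma * dyn * rng.standard_normal(spec.shape)
    return Volume(noisy), LabelVolume(labels)


def make_ground_truth_warp(
    shape, amplitude: float, sigma: float, seed: int
) -> DisplacementField:
    """Smooth random displacement field with max vector norm = ``amplitude``.

    White noise is smoothed with a zero-padded Gaussian, so the field decays
    toward the volume borders (content never leaves the volume and the
    maximum is a genuine interior bump, not a border artifact of the
    smoothing). Guaranteed fold-free: if the rescaled field folds space
    anywhere, the amplitude is reduced by 30% and the field regenerated
    (warning emitted), up to 5 times.
    """
    shape = tuple(int(n) for n in shape)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return DisplacementField.zeros(shape)
    rng = np.random.default_rng(seed)
    amp = float(amplitude)
    for _ in range(6):
        raw = rng.standard_normal((*shape, 3))
        for c in range(3):
            raw[..., c] = gaussian_filter(raw[..., c], sigma=sigma, mode="constant")
        norms = np.sqrt(np.einsum("...i,...i->...", raw, raw))
        peak = norms.max()
        if peak == 0:
            continue
        field = DisplacementField(raw * (amp / peak))
        if count_foldings(jacobian_determinant(field)) == 0:
            return field
        amp *= 0.7
        warnings.warn(
            f"ground-truth warp folded at amplitude {amp / 0.7:.2f}; retrying at {amp:.2f}"
        )
    raise RuntimeError("could not generate a fold-free warp after 5 retries")


def invert_field(u: DisplacementField, n_iter: int = 30) -> DisplacementField:
    """Fixed-point inverse of a small smooth displacement field.

    Solves v(y) = -u(y + v(y)); valid when the warp is far from folding.
    """
    shape = u.shape
    grid = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij"),
        axis=-1,
    )
    inv = np.zeros_like(u.vectors)
    for _ in range(n_iter):
        pts = (grid + inv).reshape(-1, 3)
        sampled = np.stack(
            [
                map_coordinates(u.vectors[..., c], pts.T, order=1, mode="nearest", prefilter=False)
                for c in range(3)
            ],
            axis=-1,
        )
        inv = -sampled.reshape(inv.shape)
    return DisplacementField(inv)


def make_registration_pair(
    spec: PhantomSpec,
) -> tuple[Volume, Volume, DisplacementField, LabelVolume, LabelVolume]:
    """Target, source, ground-truth field and label pair for recovery tests.

    The truth field lives on the target grid: sampling the source at
    x + truth(x) reconstructs the noise-free target. Because the phantom is
    an analytic blob sum, the target is evaluated exactly at the deformed
    coordinates — no resampling blur enters the pair, and the truth field is
    an unbiased optimum of the matching problem. Noise is added to target
    and source independently afterwards (scan/rescan noise, not interpolated
    noise).
    """
    rng = np.random.default_rng(spec.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    params = _blob_params(spec, np.random.default_rng(sub[0]))
    grid = _grid_points(spec.shape)

    src_clean, src_labels = _eval_phantom(grid, params)
    truth = make_ground_truth_warp(spec.shape, spec.warp_amplitude, spec.warp_sigma, sub[1])
    tgt_clean, tgt_labels = _eval_phantom(grid + truth.vectors.reshape(-1, 3), params)

    source_labels = LabelVolume(src_labels.reshape(spec.shape))
    target_labels = LabelVolume(tgt_labels.reshape(spec.shape))

    dyn = src_clean.max() - src_clean.min()
    noise_t = np.random.default_rng(sub[2]).standard_normal(spec.shape)
    noise_s = np.random.default_rng(sub[3]).standard_normal(spec.shape)
    target = Volume(tgt_clean.reshape(spec.shape) + spec.noise_sigma * dyn * noise_t)
    source = Volume(src_clean.reshape(spec.shape) + spec.noise_sigma * dyn * noise_s)
    return target, source, truth, target_labels, source_labels
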