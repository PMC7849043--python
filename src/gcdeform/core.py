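"""Volumetric containers, trilinear sampling, warping and the multiresolution pyramid.

Images live on regular voxel grids. All coordinates used by this package are
voxel coordinates of the grid they refer to; voxel spacing is carried as
metadata only (it affects the physical interpretation of the regularizer, not
the arithmetic). Displacement fields are stored in voxel units of their own
grid, so a vector (1, 0, 0) always means "one voxel along x at this level".

All arithmetic is done in float64; out-of-bounds sampling replicates the
border voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "Volume",
    "DisplacementField",
    "Pyramid",
    "sample_trilinear",
    "warp_volume",
    "build_pyramid",
    "upsample_field",
    "downsample_field",
]


@dataclass
class Volume:
    """A 3-D scalar image: intensity values on a regular grid plus voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape={self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class DisplacementField:
    """Dense per-voxel displacement u, defining the transform W(x) = x + u(x).

    ``vectors`` has shape (nx, ny, nz, 3); components are in voxel units of
    the grid the field is defined on (the target grid of its pyramid level).
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"displacement field must have shape (nx,ny,nz,3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite components")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], spacing=(1.0, 1.0, 1.0)) -> "DisplacementField":
        return cls(np.zeros((*shape, 3), dtype=np.float64), spacing)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing)


@dataclass
class Pyramid:
    """Target/source volume pairs ordered coarse -> fine, downsampled by 2 per level."""

    levels: list[tuple[Volume, Volume]] = field(default_factory=list)
    factor: int = 2

    def __len__(self) -> int:
        return len(self.levels)


def _sample_points(data: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``data`` at ``points`` (n, 3), border-replicated."""
    if not np.all(np.isfinite(points)):
        raise ValueError("sampling coordinates must be finite")
    return map_coordinates(data, points.T, order=1, mode="nearest", prefilter=False)


def sample_trilinear(vol: Volume, point) -> float:
    """Trilinear interpolation of a single point in voxel coordinates.

    Coordinates outside the grid are clamped to the border voxel.
    """
    point = np.asarray(point, dtype=np.float64).reshape(1, 3)
    return float(_sample_points(vol.data, point)[0])


def warp_volume(src: Volume, u: DisplacementField) -> Volume:
    """Pull-back warp: output voxel v takes the value of ``src`` at v + u(v).

    The output lives on the grid of ``u`` (the target grid).
    """
    shape = u.shape
    grid = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij"),
        axis=-1,
    )
    pts = (grid + u.vectors).reshape(-1, 3)
    out = _sample_points(src.data, pts).reshape(shape)
    return Volume(out, u.spacing)


def _downsample_volume(vol: Volume, sigma: float = 1.0) -> Volume:
    smoothed = gaussian_filter(vol.data, sigma=sigma, mode="nearest")
    dec = smoothed[::2, ::2, ::2]
    return Volume(dec, tuple(s * 2 for s in vol.spacing))


def build_pyramid(target: Volume, source: Volume, n_levels: int) -> Pyramid:
    """Gaussian pyramid (sigma = 1 voxel, decimation by 2), coarse -> fine.

    The finest level is the unmodified input pair; each coarser level halves
    every dimension (ceil rounding). Raises if a level would reduce a
    dimension below 2, naming the limiting axis.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if target.shape != source.shape:
        raise ValueError(f"target shape {target.shape} != source shape {source.shape}")
    levels: list[tuple[Volume, Volume]] = [(target, source)]
    for _ in range(n_levels - 1):
        t, s = levels[0]
        small = [i for i, n in enumerate(t.shape) if (n + 1) // 2 < 2]
        if small:
            raise ValueError(
                f"cannot build {n_levels} pyramid levels: axis {small[0]} with "
                f"{t.shape[small[0]]} voxels cannot be halved further"
            )
        levels.insert(0, (_downsample_volume(t), _downsample_volume(s)))
    return Pyramid(levels=levels)


def upsample_field(u: DisplacementField, target_shape, spacing=None) -> DisplacementField:
    """Interpolate a displacement field onto a grid about twice as fine.

    Components are trilinearly interpolated and multiplied by the per-axis
    shape ratio: vectors are stored in voxel units, so they scale with
    resolution. The ratio must lie in [1.5, 2.5] per axis (guards against
    passing mismatched pyramid levels).
    """
    target_shape = tuple(int(n) for n in target_shape)
    ratios = np.array([t / c for t, c in zip(target_shape, u.shape)])
    if np.any(ratios < 1.5) or np.any(ratios > 2.5):
        raise ValueError(
            f"shape ratio {ratios} outside [1.5, 2.5]; not adjacent pyramid levels"
        )
    coords = np.meshgrid(
        *(np.arange(n, dtype=np.float64) / r for n, r in zip(target_shape, ratios)),
        indexing="ij",
    )
    out = np.empty((*target_shape, 3), dtype=np.float64)
    for c in range(3):
        out[..., c] = ratios[c] * map_coordinates(
            u.vectors[..., c], coords, order=1, mode="nearest", prefilter=False
        )
    return DisplacementField(out, spacing or tuple(s / r for s, r in zip(u.spacing, ratios)))


def downsample_field(u: DisplacementField) -> DisplacementField:
    """Decimate a field by 2 per axis and halve its (voxel-unit) vectors."""
    dec = u.vectors[::2, ::2, ::2, :] * 0.5
    return DisplacementField(dec, tuple(s * 2 for s in u.spacing))
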