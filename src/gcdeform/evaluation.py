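"""Deformation-quality and label-overlap metrics.

Jacobian determinant maps (local volume change; negative values mean the
transform folds space), folding counts, nearest-neighbor label propagation
through a displacement field, and per-region Dice overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import DisplacementField

__all__ = [
    "LabelVolume",
    "JacobianMap",
    "jacobian_determinant",
    "count_foldings",
    "warp_labels",
    "dice_per_region",
]


@dataclass
class LabelVolume:
    """Integer region labels on a voxel grid; 0 is reserved for background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label volume contains non-integer values")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class JacobianMap:
    """Per-voxel determinant of the transform Jacobian det(I + grad u)."""

    det: np.ndarray


def jacobian_determinant(u: DisplacementField) -> JacobianMap:
    """Voxelwise Jacobian determinant of W(x) = x + u(x).

    The displacement gradient uses central differences on interior voxels and
    one-sided differences at faces, in voxel units.
    """
    if min(u.shape) < 3:
        raise ValueError(f"all dimensions must be >= 3 for gradients, got {u.shape}")
    grad = np.empty((*u.shape, 3, 3), dtype=np.float64)
    for comp in range(3):
        gx, gy, gz = np.gradient(u.vectors[..., comp])
        grad[..., comp, 0] = gx
        grad[..., comp, 1] = gy
        grad[..., comp, 2] = gz
    grad[..., 0, 0] += 1.0
    grad[..., 1, 1] += 1.0
    grad[..., 2, 2] += 1.0
    return JacobianMap(det=np.linalg.det(grad))


def count_foldings(jmap: JacobianMap, interior_only: bool = False) -> int:
    """Number of voxels where the transform folds space (determinant < 0)."""
    det = jmap.det
    if interior_only:
        det = det[1:-1, 1:-1, 1:-1]
    return int(np.count_nonzero(det < 0))


def warp_labels(labels: LabelVolume, u: DisplacementField) -> LabelVolume:
    """Propagate labels through u by nearest-neighbor sampling at v + u(v).

    Labels are categorical and must not be interpolated; out-of-bounds
    positions clamp to the border voxel.
    """
    if labels.shape != u.shape:
        raise ValueError(f"label shape {labels.shape} != field shape {u.shape}")
    grid = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in u.shape), indexing="ij"),
        axis=-1,
    )
    pts = (grid + u.vectors).reshape(-1, 3)
    out = map_coordinates(
        labels.data, pts.T, order=0, mode="nearest", prefilter=False
    ).reshape(u.shape)
    return LabelVolume(out, labels.spacing)


def dice_per_region(a: LabelVolume, b: LabelVolume, region_ids=None) -> dict[int, float]:
    """Dice overlap 2|A_l ∩ B_l| / (|A_l| + |B_l|) per region label.

    Regions absent from both volumes map to NaN (undefined, distinct from 0
    overlap); exclude NaNs when averaging.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if region_ids is None:
        region_ids = sorted(set(np.unique(a.data)) | set(np.unique(b.data)) - {0})
        region_ids = [r for r in region_ids if r != 0]
    out: dict[int, float] = {}
    for r in region_ids:
        ma = a.data == r
        mb = b.data == r
        denom = int(ma.sum()) + int(mb.sum())
        if denom == 0:
            out[int(r)] = float("nan")
        else:
            out[int(r)] = 2.0 * int(np.count_nonzero(ma & mb)) / denom
    return out
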