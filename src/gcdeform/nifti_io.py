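"""NIfTI readers and writers, YAML configuration, and the run manifest.

Scalar volumes and label volumes are plain 3-D NIfTI-1 images (.nii or
.nii.gz); displacement fields carry a trailing vector dimension of size 3 and
are stored in voxel units of their own grid (a note to that effect goes into
the run manifest). Voxel spacing is taken from the header zooms; full affine
handling is out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .core import DisplacementField, Volume
from .energy import RegistrationConfig
from .evaluation import LabelVolume
from .optimizer import SweepReport

__all__ = [
    "read_volume",
    "read_labels",
    "read_field",
    "write_volume",
    "write_labels",
    "write_field",
    "load_config",
    "RunManifest",
]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return nib.load(path)
    except Exception as exc:  # malformed header / not a NIfTI
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc


def _zooms(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) if v > 0 else 1.0 for v in z)


def read_volume(path) -> Volume:
    """Read a 3-D scalar NIfTI volume (gzipped or plain)."""
    img = _load(path)
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {data.shape}")
    return Volume(np.asarray(data, dtype=np.float64), _zooms(img))


def read_labels(path) -> LabelVolume:
    """Read an integer label NIfTI volume; non-integer data is rejected."""
    img = _load(path)
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer) and not np.allclose(
        data, np.round(data)
    ):
        raise ValueError(f"{path}: label volume contains non-integer values")
    return LabelVolume(np.round(np.asarray(data)).astype(np.int32), _zooms(img))


def read_field(path) -> DisplacementField:
    """Read a displacement field: NIfTI with trailing vector dimension 3."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    data = data.reshape([s for s in data.shape if s != 1] if data.ndim > 4 else data.shape)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a displacement field shaped (nx,ny,nz,3), got {data.shape}"
        )
    return DisplacementField(np.asarray(data, dtype=np.float64), _zooms(img))


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def write_volume(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data, _affine(vol.spacing)), str(path))


def write_labels(labels: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(labels.data.astype(np.int32), _affine(labels.spacing)), str(path))


def write_field(u: DisplacementField, path) -> None:
    nib.save(nib.Nifti1Image(u.vectors, _affine(u.spacing)), str(path))


def load_config(path) -> dict:
    """Flat key/value YAML config; keys mirror RegistrationConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    valid = set(RegistrationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to rerun a registration bit-identically."""

    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    field_units: str = "voxel units of the output grid"
    sweeps: list[dict] = field(default_factory=list)
    wall_time_s: float = 0.0
    final_energy: float = float("nan")

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = f"sha256:{_sha256(path)}"

    def add_reports(self, reports: list[SweepReport]) -> None:
        self.sweeps = [r.to_dict() for r in reports]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
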