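"""Volume containers and NIfTI I/O.

All images in the pipeline live on a fixed voxel lattice; physical
distances are always derived from the voxel spacing in millimetres, so
anisotropic grids are handled correctly even though typical inputs are
1 mm isotropic. Volumes are processed in their stored orientation; no
reorientation or resampling is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "MaskVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "check_grid_compatible",
    "require_grid_compatible",
    "GridMismatchError",
]

#: relative tolerance for grid compatibility (shapes must match exactly)
GRID_RTOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when an operation receives volumes on incompatible grids."""


@dataclass
class Volume3D:
    """A scalar 3D image with spacing (mm) and affine orientation metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values. Must not contain NaN.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine (NIfTI convention, mm).
    unit : str
        Free-text unit label, e.g. ``"intensity"``, ``"mm"``, ``"probability"``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    unit: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        spacing = self.spacing
        if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
            raise ValueError(f"voxel spacing must be positive and finite, got {spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.data).any():
            raise ValueError("volume contains NaN voxels")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "Volume3D":
        """A new volume on the same grid with different voxel values."""
        return Volume3D(data=data, affine=self.affine.copy(),
                        unit=self.unit if unit is None else unit)


@dataclass
class MaskVolume(Volume3D):
    """A binary 3D mask; values are exactly {0, 1}."""

    unit: str = "label"

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def bool_data(self) -> np.ndarray:
        return self.data.astype(bool)

    def require_nonempty(self) -> None:
        if not self.data.any():
            raise ValueError("mask is empty (no foreground voxels)")


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return img


def read_volume(path: str | Path, unit: str = "intensity") -> Volume3D:
    """Read a 3D NIfTI volume (.nii or .nii.gz).

    Rejects 4D inputs and volumes containing NaN/Inf.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D with shape {data.shape}; "
            "split 4D files into one volume per component first"
        )
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN or Inf voxels")
    return Volume3D(data=data, affine=np.asarray(img.affine), unit=unit)


def read_mask(path: str | Path) -> MaskVolume:
    """Read an integer label file as a binary mask (any nonzero voxel is 1)."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: mask contains NaN or Inf voxels")
    return MaskVolume(data=(np.asarray(data) != 0).astype(np.uint8),
                      affine=np.asarray(img.affine))


def read_memberships(path: str | Path) -> list[Volume3D]:
    """Read class membership volumes stored stacked along a 4th dimension.

    A plain 3D file is returned as a single-element list, so per-class
    files and 4D stacks are both accepted.
    """
    img = _load_nifti(path)
    data = np.asarray(np.asanyarray(img.dataobj), dtype=np.float32)
    affine = np.asarray(img.affine)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 3D or 4D memberships, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: memberships contain NaN or Inf voxels")
    return [Volume3D(data=data[..., k], affine=affine, unit="probability")
            for k in range(data.shape[-1])]


def write_volume(vol: Volume3D, path: str | Path, dtype=np.float32,
                 description: str = "") -> Path:
    """Write a volume as NIfTI-1, float32 payload by default.

    NaN values (undefined-metric sentinel) are written as 0; callers emit
    a validity mask alongside when that matters.
    """
    path = Path(path)
    data = np.asarray(vol.data, dtype=dtype)
    if np.issubdtype(data.dtype, np.floating):
        data = np.nan_to_num(data, nan=0.0)
    img = nib.Nifti1Image(data, vol.affine)
    img.header["descrip"] = description.encode()[:79]
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return path


def check_grid_compatible(a: Volume3D, b: Volume3D, rtol: float = GRID_RTOL) -> bool:
    """True iff two volumes share shape, spacing and affine within tolerance.

    Affines are compared entry-wise with an absolute floor of ``rtol`` mm so
    that a pure translation (same spacing, shifted origin) is detected.
    """
    if a.shape != b.shape:
        return False
    if not np.allclose(a.spacing, b.spacing, rtol=rtol, atol=0):
        return False
    scale = max(1.0, float(np.abs(a.affine).max()))
    return bool(np.allclose(a.affine, b.affine, rtol=rtol, atol=rtol * scale))


def require_grid_compatible(*vols: Volume3D) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    ref = vols[0]
    for v in vols[1:]:
        if not check_grid_compatible(ref, v):
            raise GridMismatchError(
                f"incompatible grids: shape/spacing/affine differ "
                f"({ref.shape}, {ref.spacing} vs {v.shape}, {v.spacing})"
            )
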