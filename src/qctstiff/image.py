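"""3D scalar images on a regular axis-aligned grid.

Two containers share the same grid contract: :class:`CTImage` holds raw
Hounsfield units, :class:`DensityImage` holds K2HPO4-equivalent density in
mg/cm^3 after calibration.  Conventions used throughout the package:

* arrays are indexed ``voxels[i, j, k]`` for the x, y, z axes;
* ``origin`` is the world coordinate (mm) of the *center* of voxel (0,0,0);
* the world position of voxel (i,j,k) is ``origin + (i,j,k) * spacing``;
* grids are "congruent" when shape, spacing and origin agree.

Orientation matrices are not modelled: synthetic volumes and the NIfTI /
MetaImage files this package writes are axis-aligned by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.asarray(v).ravel())
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class CTImage:
    """A CT volume in Hounsfield units."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError("grid dimensions must be >= 2 on each axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of every voxel center, shape (*grid, 3)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def congruent_with(self, other: "CTImage | DensityImage", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    # ---- I/O --------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTImage":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
        origin = tuple(float(x) for x in affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)

    def to_mha(self, path: str | Path) -> None:
        # SimpleITK arrays are (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        sitk.WriteImage(img, str(path))

    @classmethod
    def from_mha(cls, path: str | Path) -> "CTImage":
        img = sitk.ReadImage(str(path))
        vox = sitk.GetArrayFromImage(img).T.astype(np.float64)
        return cls(vox, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


@dataclass
class DensityImage:
    """A calibrated QCT volume in mg K2HPO4 / cm^3.

    ``calibration`` is a provenance tag (the calibration method name); values
    may be negative — clamping happens at the FE material-mapping stage.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    calibration: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    congruent_with = CTImage.congruent_with
    voxel_centers = CTImage.voxel_centers
    to_nifti = CTImage.to_nifti

    def save_with_provenance(self, path: str | Path) -> None:
        """Write NIfTI plus a sidecar JSON recording the calibration tag."""
        import json

        path = Path(path)
        self.to_nifti(path)
        sidecar = path.with_suffix("").with_suffix(".json")
        sidecar.write_text(json.dumps({"calibration": self.calibration}, indent=2))


def save_labels(labels: np.ndarray, spacing, origin, path: str | Path) -> None:
    """Write an integer label volume as NIfTI."""
    affine = np.diag([*_as_tuple3(spacing), 1.0])
    affine[:3, 3] = _as_tuple3(origin)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
    origin = tuple(float(x) for x in affine[:3, 3])
    return np.asarray(img.dataobj, dtype=np.int32), spacing, origin
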