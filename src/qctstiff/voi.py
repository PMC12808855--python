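"""Volume-of-interest isolation below the anatomic-neck resection plane.

The region feeding both the vBMD measurement and the finite-element model is
the 10 mm slab of bone directly distal to the resection plane of a stemless
humeral implant.  The workflow is: threshold the CT at HU > 225, keep the
largest connected component and fill interior holes (the trabecular center
can drop below the threshold), build a slab-shaped implicit region below the
plane, and take the Boolean intersection.  One VOI per specimen is shared by
every calibration method so that method comparisons see identical voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SegmentationError, VOIError
from .image import CTImage, DensityImage, load_labels, save_labels


@dataclass
class ResectionPlane:
    """Anatomic-neck cut plane: a point on the plane and a unit normal
    pointing distally (into the retained bone)."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.point = tuple(float(x) for x in self.point)  # type: ignore[assignment]
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("normal must be nonzero")
            n = n / norm
        self.normal = tuple(float(x) for x in n)  # type: ignore[assignment]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance along the (distal) normal; >=0 is below the cut."""
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.point)) @ np.asarray(self.normal)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"point": list(self.point), "normal": list(self.normal)})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResectionPlane":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["point"]), tuple(d["normal"]))


@dataclass
class Slab:
    """Implicit cuboid region: the space between the resection plane and its
    parallel offset ``depth`` mm along the normal, laterally bounded by a
    ``lateral_extent`` x ``lateral_extent`` square in the plane.

    The lateral extent must exceed the bone cross-section so that the Boolean
    intersection with the bone mask governs the lateral boundary.
    """

    plane: ResectionPlane
    depth: float
    lateral_extent: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("slab depth must be > 0")
        if self.lateral_extent <= 0:
            raise ValueError("lateral extent must be > 0")
        # in-plane orthonormal frame for the lateral bound
        n = np.asarray(self.plane.normal)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, seed)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        self._frame = (u, v)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        rel = p - np.asarray(self.plane.point)
        d = rel @ np.asarray(self.plane.normal)
        u, v = self._frame
        half = self.lateral_extent / 2.0
        return (
            (d >= 0.0)
            & (d <= self.depth)
            & (np.abs(rel @ u) <= half)
            & (np.abs(rel @ v) <= half)
        )


@dataclass
class VOIMask:
    """Boolean voxel mask of the sub-resection volume of interest."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    depth: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise VOIError("VOI mask is empty")

    @property
    def shape(self):
        return self.mask.shape

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, path: str | Path) -> None:
        save_labels(self.mask.astype(np.int16), self.spacing, self.origin, path)

    @classmethod
    def from_nifti(cls, path: str | Path, depth: float) -> "VOIMask":
        arr, spacing, origin = load_labels(path)
        return cls(arr > 0, spacing, origin, depth)


def segment_bone(image: CTImage, threshold: float = 225.0) -> np.ndarray:
    """Global-threshold bone segmentation.

    Voxels with HU strictly above ``threshold`` are kept; the largest
    26-connected component survives (discarding e.g. phantom rods and the
    scapula) and interior holes are filled so the low-attenuating trabecular
    center stays part of the bone.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    raw = image.voxels > threshold
    if not raw.any():
        raise SegmentationError(f"no voxel above {threshold} HU")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        raw = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(raw)


def build_voi(plane: ResectionPlane, depth: float = 10.0,
              lateral_extent: float = 200.0) -> Slab:
    """Build the implicit slab region ``depth`` mm below the resection plane."""
    return Slab(plane, depth, lateral_extent)


def intersect(bone: np.ndarray, slab: Slab, spacing, origin) -> VOIMask:
    """Boolean intersection of the bone mask with the slab (voxel-center test)."""
    bone = np.asarray(bone, dtype=bool)
    if not bone.any():
        raise VOIError("bone mask is empty")
    grid = CTImage(np.zeros(bone.shape), spacing, origin)
    centers = grid.voxel_centers().reshape(-1, 3)
    inside = slab.contains(centers).reshape(bone.shape)
    voi = bone & inside
    if not voi.any():
        raise VOIError("slab does not intersect the bone mask")
    d = slab.plane.signed_distance(centers[voi.ravel()])
    achieved_depth = float(d.max() - d.min())
    return VOIMask(voi, tuple(grid.spacing), tuple(grid.origin),
                   depth=min(slab.depth, achieved_depth + max(grid.spacing)))


def mean_vbmd(density: DensityImage, voi: VOIMask) -> float:
    """Mean calibrated density (mg K2HPO4/cm^3) over the VOI voxels."""
    if density.shape != voi.shape:
        raise VOIError("density image and VOI mask are not congruent")
    if not voi.mask.any():
        raise VOIError("VOI mask is empty")
    return float(density.voxels[voi.mask].mean())
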