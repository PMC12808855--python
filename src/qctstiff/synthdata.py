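"""Synthetic CT specimens with known ground truth.

No public CT dataset with an in-scan K2HPO4 phantom and a defined humeral
resection plane exists, so the pipeline is exercised on generated volumes
that carry: a proximal-humerus-like bone (hemispherical head on a truncated
conical metaphysis, ~1200 HU cortical shell, spatially varying trabecular
interior), surrounding skeletal muscle and subcutaneous adipose layers, air
background, and a multi-rod K2HPO4 calibration phantom below the anatomy.

Inside bone (and the phantom rods) the true equivalent density and the ideal
HU are linked by a configurable *linear ground-truth law*::

    density [mg K2HPO4/cm^3] = slope * HU + intercept

so that a correct calibration fit must recover exactly this law in the
noiseless case — every downstream recovery test reduces to checkable
arithmetic.  A :class:`ScannerModel` then corrupts the ideal HU volume with
a global gain/offset drift and i.i.d. Gaussian noise, the variability that
motivates per-scan density calibration in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, GeometryError
from .image import CTImage
from .voi import ResectionPlane

# integer tissue labels; phantom rod i is PHANTOM_ROD_BASE + i
AIR, ADIPOSE, MUSCLE, TRABECULAR, CORTICAL = 0, 1, 2, 3, 4
PHANTOM_ROD_BASE = 10

TISSUE_NAMES = {AIR: "air", ADIPOSE: "adipose", MUSCLE: "muscle",
                TRABECULAR: "trabecular", CORTICAL: "cortical"}

# Expected tissue HU (air, adipose, muscle from standard radiology reference
# values; cortical at the center of the 1000-1500 HU window).
DEFAULT_TISSUE_HU = {"air": -1000.0, "adipose": -60.0, "muscle": 40.0,
                     "cortical": 1200.0}


@dataclass
class ScannerModel:
    """Global affine HU drift plus i.i.d. Gaussian noise.

    observed HU = gain * ideal HU + offset + N(0, noise_sd)
    """

    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigError("scanner gain must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def apply(self, ideal_hu: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        out = self.gain * ideal_hu + self.offset
        if self.noise_sd > 0:
            out = out + rng.normal(0.0, self.noise_sd, size=ideal_hu.shape)
        return out


@dataclass
class SpecimenSpec:
    """Parametric description of one synthetic specimen.

    Lengths in mm, densities in mg K2HPO4/cm^3, HU dimensionless.
    """

    head_radius: float = 18.0
    cortical_thickness: float = 2.5
    trabecular_density_range: tuple[float, float] = (100.0, 400.0)
    tissue_mean_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    phantom_rod_densities: tuple = (0.0, 100.0, 200.0, 400.0, 600.0)
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # ground-truth linear law: density = slope * HU + intercept
    density_hu_slope: float = 0.75
    density_hu_intercept: float = 0.0
    include_phantom: bool = True
    rod_radius: float = 3.0
    muscle_thickness: float = 6.0
    adipose_thickness: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.trabecular_density_range
        if not lo < hi:
            raise ConfigError("trabecular density range must satisfy low < high")
        if not 0 < self.cortical_thickness < self.head_radius:
            raise ConfigError("cortical_thickness must be in (0, head_radius)")
        if self.density_hu_slope <= 0:
            raise ConfigError("ground-truth density/HU slope must be > 0")
        if len(self.phantom_rod_densities) >= 2:
            d = np.diff(self.phantom_rod_densities)
            if not np.all(d > 0):
                raise ConfigError("phantom rod densities must be strictly increasing")

    # ground-truth law and its inverse -------------------------------------
    def hu_to_density(self, hu):
        return self.density_hu_slope * np.asarray(hu, float) + self.density_hu_intercept

    def density_to_hu(self, density):
        return (np.asarray(density, float) - self.density_hu_intercept) / self.density_hu_slope

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpecimenSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("trabecular_density_range", "phantom_rod_densities",
                  "grid_shape", "spacing"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    density_field: np.ndarray        # true equivalent density, mg/cm^3
    tissue_labels: np.ndarray        # integer labels, congruent grid
    resection_plane: ResectionPlane
    rod_densities: tuple
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.density_field.shape != self.tissue_labels.shape:
            raise ValueError("density and label grids must be congruent")
        if len(self.rod_densities) >= 2 and not np.all(np.diff(self.rod_densities) > 0):
            raise ValueError("rod densities must be strictly increasing")

    def label_mask(self, label: int) -> np.ndarray:
        return self.tissue_labels == label

    def rod_mask(self, i: int) -> np.ndarray:
        return self.tissue_labels == PHANTOM_ROD_BASE + i


def _world_axes(shape, spacing, origin=(0.0, 0.0, 0.0)):
    return [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]


def _build_anatomy(spec: SpecimenSpec):
    """Label grid + true density + ideal HU for the anatomy (no phantom)."""
    from scipy import ndimage

    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    Lz = nz * sz
    xs, ys, zs = _world_axes(spec.grid_shape, spec.spacing)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    cx, cy = xs.mean(), ys.mean()
    z_eq = zs[0] + 0.60 * Lz                       # resection plane height
    R = spec.head_radius
    if z_eq + R + 2.0 * sz > zs[-1]:
        raise GeometryError("grid too small for head_radius (head cap clipped)")
    # always keep the phantom bay free so rods can be embedded post hoc
    rod_clearance = 2.0 * spec.rod_radius + 4.0
    meta_len = z_eq - (zs[0] + rod_clearance)
    if meta_len < 12.0:
        raise GeometryError("grid too small for metaphysis + phantom clearance")

    r_xy = np.hypot(X - cx, Y - cy)
    head = (np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - z_eq) ** 2) <= R) & (Z >= z_eq)
    frac = np.clip((z_eq - Z) / meta_len, 0.0, 1.0)   # 0 at plane, 1 at base
    cone_r = R * (1.0 - 0.4 * frac)
    cone = (Z < z_eq) & (Z >= z_eq - meta_len) & (r_xy <= cone_r)
    bone = head | cone

    # cortical shell: bone voxels within cortical_thickness of the surface
    dist_in = ndimage.distance_transform_edt(bone, sampling=spec.spacing)
    cortical = bone & (dist_in <= spec.cortical_thickness)
    trabecular = bone & ~cortical

    dist_out = ndimage.distance_transform_edt(~bone, sampling=spec.spacing)
    muscle = ~bone & (dist_out <= spec.muscle_thickness)
    adipose = (~bone & ~muscle
               & (dist_out <= spec.muscle_thickness + spec.adipose_thickness))

    labels = np.full(spec.grid_shape, AIR, dtype=np.int32)
    labels[adipose] = ADIPOSE
    labels[muscle] = MUSCLE
    labels[trabecular] = TRABECULAR
    labels[cortical] = CORTICAL

    # soft tissues: ideal HU from the spec table, density via the gt law
    hu = np.full(spec.grid_shape, spec.tissue_mean_hu["air"], dtype=np.float64)
    hu[adipose] = spec.tissue_mean_hu["adipose"]
    hu[muscle] = spec.tissue_mean_hu["muscle"]
    hu[cortical] = spec.tissue_mean_hu["cortical"]

    # trabecular: radial density gradient (densest near the cortex), HU from
    # the inverse gt law so calibration recovery is exact
    lo, hi = spec.trabecular_density_range
    local_r = np.where(Z >= z_eq, R, cone_r)
    t = np.clip(r_xy / np.maximum(local_r, 1e-9), 0.0, 1.0)
    trab_density = lo + (hi - lo) * t
    density = spec.hu_to_density(hu)
    density[trabecular] = trab_density[trabecular]
    hu[trabecular] = spec.density_to_hu(trab_density[trabecular])

    plane = ResectionPlane(point=(cx, cy, z_eq), normal=(0.0, 0.0, -1.0))
    return labels, density, hu, plane


def embed_phantom(image: CTImage, truth: GroundTruth,
                  rod_densities, rod_hu, rod_radius: float = 3.0) -> tuple[CTImage, GroundTruth]:
    """Paint cylindrical calibration rods (axis along y) into the image.

    Rods are placed in a row below the anatomy; each is painted with its
    ideal HU and labelled ``PHANTOM_ROD_BASE + i`` in the ground truth.
    Rod HU values may coincide (a degenerate phantom is accepted here and
    flagged by the calibration fit downstream).
    """
    rod_densities = tuple(float(d) for d in rod_densities)
    rod_hu = tuple(float(h) for h in rod_hu)
    if len(rod_densities) != len(rod_hu) or len(rod_densities) < 2:
        raise ConfigError("need matching rod density/HU lists of length >= 2")

    shape = image.shape
    xs, ys, zs = _world_axes(shape, image.spacing, image.origin)
    X, Z = np.meshgrid(xs, zs, indexing="ij")       # rods extend along full y
    n = len(rod_densities)
    z_rod = zs[0] + rod_radius + 1.0
    pitch = 2.0 * rod_radius + 2.0
    x0 = xs.mean() - pitch * (n - 1) / 2.0
    if x0 - rod_radius < xs[0] or x0 + pitch * (n - 1) + rod_radius > xs[-1]:
        raise GeometryError("phantom rods do not fit across the grid")
    if np.any(truth.tissue_labels[:, :, zs <= z_rod + rod_radius] >= TRABECULAR):
        raise GeometryError("phantom rod region overlaps the anatomy")

    vox = image.voxels.copy()
    labels = truth.tissue_labels.copy()
    density = truth.density_field.copy()
    for i, (d, h) in enumerate(zip(rod_densities, rod_hu)):
        in_rod_2d = (X - (x0 + i * pitch)) ** 2 + (Z - z_rod) ** 2 <= rod_radius ** 2
        in_rod = np.repeat(in_rod_2d[:, None, :], shape[1], axis=1)
        if (labels[in_rod] >= PHANTOM_ROD_BASE).any():
            raise GeometryError("overlapping rod placement")
        vox[in_rod] = h
        labels[in_rod] = PHANTOM_ROD_BASE + i
        density[in_rod] = d

    new_truth = GroundTruth(density, labels, truth.resection_plane,
                            rod_densities, truth.spacing, truth.origin)
    return CTImage(vox, image.spacing, image.origin), new_truth


def generate_specimen(spec: SpecimenSpec,
                      scanner: ScannerModel | None = None) -> tuple[CTImage, GroundTruth]:
    """Generate one synthetic CT specimen plus its ground truth.

    The ideal (noise-free, drift-free) HU volume is built from the label
    field, the phantom is embedded, and the scanner model is applied last —
    so rods and tissues see the same drift and noise, exactly as an in-scan
    phantom would.  Identical spec + scanner seed gives bit-identical output.
    """
    scanner = scanner or ScannerModel()
    labels, density, hu, plane = _build_anatomy(spec)
    truth = GroundTruth(density, labels, plane, tuple(spec.phantom_rod_densities),
                        tuple(spec.spacing), (0.0, 0.0, 0.0))
    ideal = CTImage(hu, spec.spacing, (0.0, 0.0, 0.0))
    if spec.include_phantom:
        rod_hu = spec.density_to_hu(np.asarray(spec.phantom_rod_densities))
        ideal, truth = embed_phantom(ideal, truth, spec.phantom_rod_densities,
                                     rod_hu, spec.rod_radius)
    observed = CTImage(scanner.apply(ideal.voxels), spec.spacing, (0.0, 0.0, 0.0))
    return observed, truth


@dataclass
class CohortDistribution:
    """Per-specimen parameter ranges for a synthetic cohort.

    ``gain_range`` and ``offset_range`` model scan-to-scan HU drift;
    ``density_scale_range`` scales each specimen's trabecular density range,
    emulating the between-donor BMD variation of a cadaveric cohort.
    """

    gain_range: tuple[float, float] = (0.95, 1.05)
    offset_range: tuple[float, float] = (-20.0, 20.0)
    noise_sd: float = 10.0
    density_scale_range: tuple[float, float] = (0.75, 1.25)

    def __post_init__(self) -> None:
        for name in ("gain_range", "offset_range", "density_scale_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigError(f"{name} is empty (high < low)")


def cohort(spec_template: SpecimenSpec, n: int,
           distribution: CohortDistribution | None = None,
           seed: int = 0):
    """Generate ``n`` specimens with reproducibly drawn scanner/density params.

    Returns a list of ``(CTImage, GroundTruth, info-dict)``; per-specimen
    seeds are derived deterministically from the master seed.
    """
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    dist = distribution or CohortDistribution()
    rng = np.random.default_rng(seed)
    gains = rng.uniform(*dist.gain_range, n)
    offsets = rng.uniform(*dist.offset_range, n)
    scales = rng.uniform(*dist.density_scale_range, n)
    seeds = rng.integers(0, 2**31 - 1, n)

    out = []
    for i in range(n):
        lo, hi = spec_template.trabecular_density_range
        spec = replace(spec_template,
                       trabecular_density_range=(lo * scales[i], hi * scales[i]))
        scanner = ScannerModel(gain=float(gains[i]), offset=float(offsets[i]),
                               noise_sd=dist.noise_sd, seed=int(seeds[i]))
        img, truth = generate_specimen(spec, scanner)
        out.append((img, truth, {
            "specimen_id": f"S{i:03d}", "gain": float(gains[i]),
            "offset": float(offsets[i]), "noise_sd": dist.noise_sd,
            "density_scale": float(scales[i]), "seed": int(seeds[i]),
        }))
    return out
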