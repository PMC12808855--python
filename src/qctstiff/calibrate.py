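"""HU -> K2HPO4-equivalent density calibration.

Two routes produce the same linear model ``density = slope * HU + intercept``:

* **Phantom (ROD)** — ordinary least squares of in-scan rod mean HU against
  the rods' known K2HPO4 densities (optionally after a water correction),
  fitted as HU-on-density and inverted.
* **Internal (phantomless)** — the same fit on referent *tissues* instead of
  rods: air (A), subcutaneous adipose (Ad), skeletal muscle (M) sampled as
  ROI means, plus a cortical-bone reference (C) taken from the HU window
  1000-1500.  The three combinations studied are AAdC, AAdCM and ACM.

Both routes share one fitting routine, so identical (HU, density) point sets
give identical models.  Reference equivalent densities for the internal
tissues are configuration, not physics: the defaults in
:func:`default_reference_table` are implementation-chosen to lie on the
synthetic ground-truth law and must be replaced for real scanners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, CorticalReferenceError, DegenerateFitError, ROIError
from .image import CTImage, DensityImage
from .synthdata import DEFAULT_TISSUE_HU

WATER_DENSITY_MG_CM3 = 1000.0

COMBINATIONS: dict[str, tuple[str, ...]] = {
    "AAdC": ("air", "adipose", "cortical"),
    "AAdCM": ("air", "adipose", "cortical", "muscle"),
    "ACM": ("air", "cortical", "muscle"),
}

METHODS = ("PHANTOM", "AAdC", "AAdCM", "ACM")


@dataclass
class TissueSample:
    """Summary of one ROI: which tissue, mean/SD HU, and voxel count."""

    tissue: str
    mean_hu: float
    sd_hu: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ROIError("voxel_count must be >= 1")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")


@dataclass
class ReferenceTable:
    """Per-tissue expected HU and assigned reference equivalent density.

    ``entries`` maps tissue name -> (expected_hu, reference_density
    [mg K2HPO4/cm^3]).
    """

    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        dens = {round(v[1], 12) for v in self.entries.values()}
        if len(self.entries) < 2 or len(dens) < 2:
            raise ConfigError("reference table needs >= 2 tissues with distinct densities")

    def expected_hu(self, tissue: str) -> float:
        return self.entries[tissue][0]

    def reference_density(self, tissue: str) -> float:
        return self.entries[tissue][1]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {t: {"expected_hu": v[0], "reference_density": v[1]}
             for t, v in self.entries.items()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTable":
        d = yaml.safe_load(Path(path).read_text())
        return cls({t: (float(v["expected_hu"]), float(v["reference_density"]))
                    for t, v in d.items()})


def default_reference_table(slope: float = 0.75, intercept: float = 0.0,
                            tissue_hu: dict | None = None) -> ReferenceTable:
    """Reference table whose densities lie on ``density = slope*HU + intercept``.

    Implementation-chosen defaults (the original internal-calibration
    literature does not publish its equivalent-density assignments); matched
    to the synthetic ground-truth law so noiseless recovery is exact.
    """
    hu = tissue_hu or DEFAULT_TISSUE_HU
    return ReferenceTable({t: (h, slope * h + intercept) for t, h in hu.items()})


@dataclass
class CalibrationModel:
    """Linear HU -> density map with fit diagnostics."""

    method: str
    slope: float                 # (mg K2HPO4/cm^3) per HU
    intercept: float             # mg K2HPO4/cm^3
    r_squared: float
    samples: list[TissueSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise DegenerateFitError("non-finite calibration coefficients")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))

    def predict(self, hu):
        return self.slope * np.asarray(hu, float) + self.intercept

    def to_dict(self) -> dict:
        return {"method": self.method, "slope": self.slope,
                "intercept": self.intercept, "r_squared": self.r_squared}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# sampling

def sample_roi(image: CTImage, mask: np.ndarray, tissue: str) -> TissueSample:
    """Mean/SD HU over a boolean ROI mask (sample SD, n-1 denominator)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ROIError("ROI mask is not congruent with the image")
    vals = image.voxels[mask]
    if vals.size == 0:
        raise ROIError(f"empty ROI for tissue '{tissue}'")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return TissueSample(tissue, float(vals.mean()), sd, int(vals.size))


def cortical_reference(image: CTImage, bone_mask: np.ndarray,
                       window: tuple[float, float] = (1000.0, 1500.0),
                       mode: str = "max") -> TissueSample:
    """Cortical-bone HU reference from the windowed bone voxels.

    ``mode='max'`` (default) returns the highest HU among bone voxels inside
    ``window`` — the literal thresholding rule.  ``mode='mean'`` returns the
    mean of the windowed voxels, an unbiased alternative when cortical HU is
    nominally uniform and the max would only track the noise extreme.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if bone_mask.shape != image.shape:
        raise ROIError("bone mask is not congruent with the image")
    if not bone_mask.any():
        raise ROIError("bone mask is empty")
    vals = image.voxels[bone_mask]
    lo, hi = window
    in_win = vals[(vals >= lo) & (vals <= hi)]
    if in_win.size == 0:
        raise CorticalReferenceError(
            f"no bone voxel inside the [{lo}, {hi}] HU window")
    if mode == "max":
        return TissueSample("cortical", float(in_win.max()), 0.0, 1)
    if mode == "mean":
        sd = float(in_win.std(ddof=1)) if in_win.size > 1 else 0.0
        return TissueSample("cortical", float(in_win.mean()), sd, int(in_win.size))
    raise ConfigError(f"unknown cortical reference mode '{mode}'")


# ---------------------------------------------------------------------------
# fitting

def _fit_line(hu: np.ndarray, density: np.ndarray, method: str,
              samples: list[TissueSample]) -> CalibrationModel:
    """OLS of HU on density, inverted to density = slope*HU + intercept."""
    hu = np.asarray(hu, float)
    density = np.asarray(density, float)
    if hu.size < 2:
        raise DegenerateFitError("need at least two calibration points")
    if np.ptp(hu) == 0:
        raise DegenerateFitError("identical HU across calibration points")
    if np.ptp(density) == 0:
        raise DegenerateFitError("identical reference density across points")
    a, b = np.polyfit(density, hu, 1)       # hu = a*density + b
    if a <= 0:
        raise DegenerateFitError("non-positive HU/density slope")
    slope, intercept = 1.0 / a, -b / a
    if hu.size == 2:
        r2 = 1.0
    else:
        r = np.corrcoef(hu, density)[0, 1]
        r2 = float(r * r)
    return CalibrationModel(method, float(slope), float(intercept), r2, samples)


def fit_phantom(rod_samples: list[TissueSample],
                rod_reference,
                water_correction: bool = False) -> CalibrationModel:
    """Fit the phantom (ROD) calibration.

    ``rod_reference`` is a list of K2HPO4 densities, or of
    ``(density, water_equivalent_density)`` pairs when ``water_correction``
    is enabled; the correction subtracts ``water_equivalent - 1000`` mg/cm^3
    from each rod's density axis before fitting (an approximation of the
    vendor manual's water correction, which is not published).
    """
    ref = [r if np.ndim(r) else (float(r), WATER_DENSITY_MG_CM3)
           for r in rod_reference]
    if len(rod_samples) != len(ref):
        raise ConfigError("rod sample/reference length mismatch")
    if len(rod_samples) < 2:
        raise DegenerateFitError("need >= 2 rods")
    density = np.array([d for d, _ in ref], float)
    if water_correction:
        density = density - (np.array([w for _, w in ref], float)
                             - WATER_DENSITY_MG_CM3)
    hu = np.array([s.mean_hu for s in rod_samples], float)
    return _fit_line(hu, density, "PHANTOM", list(rod_samples))


def fit_internal(samples: list[TissueSample], table: ReferenceTable,
                 combination: str) -> CalibrationModel:
    """Fit an internal calibration for one referent-tissue combination."""
    if combination not in COMBINATIONS:
        raise ConfigError(f"unknown combination '{combination}'")
    needed = COMBINATIONS[combination]
    by_tissue = {s.tissue: s for s in samples}
    missing = [t for t in needed if t not in by_tissue]
    if missing:
        raise ConfigError(f"combination {combination} is missing tissue(s): {missing}")
    for t in needed:
        if t not in table.entries:
            raise ConfigError(f"reference table has no density for '{t}'")
    used = [by_tissue[t] for t in needed]
    hu = np.array([s.mean_hu for s in used], float)
    density = np.array([table.reference_density(t) for t in needed], float)
    return _fit_line(hu, density, combination, used)


def apply_calibration(image: CTImage, model: CalibrationModel) -> DensityImage:
    """Voxelwise affine HU -> density map, tagged with the model's method."""
    return DensityImage(model.predict(image.voxels), image.spacing,
                        image.origin, calibration=model.method)


# ---------------------------------------------------------------------------
# QC

def validate_samples(samples: list[TissueSample], table: ReferenceTable,
                     tolerance_hu: float = 100.0) -> list[dict]:
    """Flag tissues whose measured mean HU strays from the expected value.

    Never aborts — returns one record per sample with an ``ok`` flag, so the
    cohort driver can log QC failures and keep running.
    """
    report = []
    for s in samples:
        expected = table.expected_hu(s.tissue) if s.tissue in table.entries else None
        ok = expected is not None and abs(s.mean_hu - expected) <= tolerance_hu
        report.append({"tissue": s.tissue, "mean_hu": s.mean_hu,
                       "expected_hu": expected, "tolerance_hu": tolerance_hu,
                       "ok": bool(ok)})
    return report
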