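"""Cohort pipeline: generate -> calibrate -> voi -> fem -> agree.

Each stage reads the previous stage's files from the run directory and
writes its own, so any stage can be re-run or inspected in isolation; the
``all`` entry chains them.  Layout of a run directory::

    run/
      manifest.json            config + seed + package version
      cohort.csv               per-specimen scanner draw
      specimens/S000/ct.nii.gz, labels.nii.gz, gt_density.nii.gz, plane.json
      specimens/S000/calibrations.json, samples.csv
      specimens/S000/voi.nii.gz
      vbmd.csv                 (specimen_id, method, vbmd)
      stiffness.csv            (specimen_id, method, F_N, A_mm2, stress_MPa,
                                stiffness_MPa)
      agreement.json / agreement.csv
      failures.csv             specimens that failed a stage (run continues)

Per-specimen failures are logged and skipped; the run only fails if every
specimen fails or the configuration is invalid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (CalibrationModel, ReferenceTable, apply_calibration,
                        cortical_reference, default_reference_table,
                        fit_internal, fit_phantom, sample_roi,
                        validate_samples)
from .errors import ConfigError, QCTStiffError
from .femstiff import FEConfig, build_voi_mesh, run_fem
from .image import CTImage, DensityImage, load_labels, save_labels
from .synthdata import (ADIPOSE, AIR, CORTICAL, MUSCLE, PHANTOM_ROD_BASE,
                        TRABECULAR, CohortDistribution, SpecimenSpec, cohort)
from .voi import ResectionPlane, VOIMask, build_voi, intersect, mean_vbmd, segment_bone

log = logging.getLogger("qctstiff")

TRUTH_METHOD = "TRUTH"


@dataclass
class RunConfig:
    """Everything needed to reproduce a cohort run."""

    n_specimens: int = 20
    seed: int = 0
    spec: SpecimenSpec = field(default_factory=SpecimenSpec)
    distribution: CohortDistribution = field(default_factory=CohortDistribution)
    reference_table: ReferenceTable | None = None
    combinations: tuple[str, ...] = ("AAdC", "AAdCM", "ACM")
    water_correction: bool = False
    cortical_mode: str = "mean"     # "max" is the literal clinical rule; see docs
    cortical_window: tuple[float, float] = (1000.0, 1500.0)
    bone_threshold_hu: float = 225.0
    voi_depth: float = 10.0
    lateral_extent: float = 200.0
    fe: FEConfig = field(default_factory=FEConfig)
    with_fem: bool = True
    internal_offset_mg_cm3: float = 0.0   # injected offset for validation runs
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fe.strain <= 0:
            raise ConfigError("strain must be > 0")
        if self.voi_depth <= 0:
            raise ConfigError("VOI depth must be > 0")
        if len(self.combinations) == 0:
            raise ConfigError("at least one calibration method must be enabled")
        if self.n_specimens < 1:
            raise ConfigError("n_specimens must be >= 1")
        if self.reference_table is None:
            self.reference_table = default_reference_table(
                self.spec.density_hu_slope, self.spec.density_hu_intercept,
                self.spec.tissue_mean_hu)

    def to_dict(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, ReferenceTable):
                return o.entries
            if isinstance(o, tuple):
                return list(o)
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        return {k: enc(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "spec" in d:
            s = d["spec"]
            for k in ("trabecular_density_range", "phantom_rod_densities",
                      "grid_shape", "spacing"):
                if k in s:
                    s[k] = tuple(s[k])
            d["spec"] = SpecimenSpec(**s)
        if "distribution" in d:
            dd = d["distribution"]
            for k in ("gain_range", "offset_range", "density_scale_range"):
                if k in dd:
                    dd[k] = tuple(dd[k])
            d["distribution"] = CohortDistribution(**dd)
        if "fe" in d:
            d["fe"] = FEConfig(**d["fe"])
        if "reference_table" in d and d["reference_table"] is not None:
            d["reference_table"] = ReferenceTable(
                {t: tuple(v) for t, v in d["reference_table"].items()})
        for k in ("combinations", "cortical_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# per-specimen building blocks (also usable in-memory, without files)

def calibrate_specimen(image: CTImage, labels: np.ndarray, cfg: RunConfig,
                       rod_densities) -> tuple[dict[str, CalibrationModel], list]:
    """Fit phantom + all configured internal calibrations for one specimen.

    ROI masks come from the ground-truth label volume (synthetic stand-in for
    the operator-drawn ROIs); the cortical reference comes from the bone
    labels through the configured HU window rule.
    """
    rods = sorted(int(v) for v in np.unique(labels) if v >= PHANTOM_ROD_BASE)
    models: dict[str, CalibrationModel] = {}
    rod_samples = [sample_roi(image, labels == r, f"rod_{r - PHANTOM_ROD_BASE}")
                   for r in rods]
    if len(rod_samples) >= 2:
        models["PHANTOM"] = fit_phantom(rod_samples, list(rod_densities),
                                        water_correction=cfg.water_correction)

    tissue_samples = [
        sample_roi(image, labels == AIR, "air"),
        sample_roi(image, labels == ADIPOSE, "adipose"),
        sample_roi(image, labels == MUSCLE, "muscle"),
    ]
    bone_mask = (labels == TRABECULAR) | (labels == CORTICAL)
    tissue_samples.append(cortical_reference(image, bone_mask,
                                             cfg.cortical_window,
                                             mode=cfg.cortical_mode))
    for combo in cfg.combinations:
        m = fit_internal(tissue_samples, cfg.reference_table, combo)
        if cfg.internal_offset_mg_cm3:
            m = CalibrationModel(m.method, m.slope,
                                 m.intercept + cfg.internal_offset_mg_cm3,
                                 m.r_squared, m.samples)
        models[combo] = m
    return models, rod_samples + tissue_samples


def measure_specimen(image: CTImage, models: dict[str, CalibrationModel],
                     plane: ResectionPlane, cfg: RunConfig,
                     gt_density: np.ndarray | None = None):
    """Shared VOI + per-method vBMD (+ optional ground-truth vBMD)."""
    bone = segment_bone(image, cfg.bone_threshold_hu)
    slab = build_voi(plane, cfg.voi_depth, cfg.lateral_extent)
    voi = intersect(bone, slab, image.spacing, image.origin)
    vbmd = {}
    for method, model in models.items():
        vbmd[method] = mean_vbmd(apply_calibration(image, model), voi)
    if gt_density is not None:
        vbmd[TRUTH_METHOD] = float(gt_density[voi.mask].mean())
    return voi, vbmd


def fem_specimen(image: CTImage, models: dict[str, CalibrationModel],
                 voi: VOIMask, plane: ResectionPlane, cfg: RunConfig) -> dict:
    """One FE solve per calibration method, sharing the specimen's mesh."""
    tet = build_voi_mesh(voi, plane, cfg.fe)
    out = {}
    for method, model in models.items():
        density = apply_calibration(image, model)
        out[method] = run_fem(density, voi, cfg.fe, plane, tet=tet)
    return out


# ---------------------------------------------------------------------------
# file-based stages

def _specdirs(outdir: Path) -> list[Path]:
    root = outdir / "specimens"
    if not root.is_dir():
        raise ConfigError(f"missing upstream artifacts: {root} (run 'generate')")
    return sorted(p for p in root.iterdir() if p.is_dir())


def _require(path: Path) -> Path:
    if not path.exists():
        raise ConfigError(f"missing upstream artifact: {path}")
    return path


def stage_generate(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, truth, info in cohort(cfg.spec, cfg.n_specimens,
                                   cfg.distribution, cfg.seed):
        sdir = outdir / "specimens" / info["specimen_id"]
        sdir.mkdir(parents=True, exist_ok=True)
        img.to_nifti(sdir / "ct.nii.gz")
        save_labels(truth.tissue_labels, truth.spacing, truth.origin,
                    sdir / "labels.nii.gz")
        DensityImage(truth.density_field, truth.spacing, truth.origin,
                     calibration=TRUTH_METHOD).to_nifti(sdir / "gt_density.nii.gz")
        truth.resection_plane.to_json(sdir / "plane.json")
        rows.append(info)
        log.info("generated %s", info["specimen_id"])
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    cfg.spec.to_yaml(outdir / "spec.yaml")
    _write_manifest(cfg, outdir)


def stage_calibrate(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    failures = []
    for sdir in _specdirs(outdir):
        sid = sdir.name
        try:
            image = CTImage.from_nifti(_require(sdir / "ct.nii.gz"))
            labels, _, _ = load_labels(_require(sdir / "labels.nii.gz"))
            models, samples = calibrate_specimen(
                image, labels, cfg, cfg.spec.phantom_rod_densities)
            (sdir / "calibrations.json").write_text(json.dumps(
                {m: mod.to_dict() for m, mod in models.items()}, indent=2))
            pd.DataFrame([s.__dict__ for s in samples]).to_csv(
                sdir / "samples.csv", index=False)
            qc = validate_samples([s for s in samples if s.tissue in
                                   cfg.reference_table.entries],
                                  cfg.reference_table)
            for rec in qc:
                if not rec["ok"]:
                    log.warning("%s QC: tissue %s at %.1f HU, expected %.1f",
                                sid, rec["tissue"], rec["mean_hu"],
                                rec["expected_hu"])
        except QCTStiffError as exc:
            log.error("%s calibrate failed: %s", sid, exc)
            failures.append({"specimen_id": sid, "stage": "calibrate",
                             "error": str(exc)})
    _record_failures(outdir, failures, "calibrate")


def _load_models(sdir: Path) -> dict[str, CalibrationModel]:
    d = json.loads(_require(sdir / "calibrations.json").read_text())
    return {m: CalibrationModel(v["method"], v["slope"], v["intercept"],
                                v["r_squared"]) for m, v in d.items()}


def stage_voi(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows, failures = [], []
    for sdir in _specdirs(outdir):
        sid = sdir.name
        try:
            image = CTImage.from_nifti(_require(sdir / "ct.nii.gz"))
            plane = ResectionPlane.from_json(_require(sdir / "plane.json"))
            models = _load_models(sdir)
            gt_path = sdir / "gt_density.nii.gz"
            gt = (CTImage.from_nifti(gt_path).voxels if gt_path.exists() else None)
            voi, vbmd = measure_specimen(image, models, plane, cfg, gt)
            voi.to_nifti(sdir / "voi.nii.gz")
            rows += [{"specimen_id": sid, "method": m, "vbmd": v}
                     for m, v in vbmd.items()]
        except QCTStiffError as exc:
            log.error("%s voi failed: %s", sid, exc)
            failures.append({"specimen_id": sid, "stage": "voi",
                             "error": str(exc)})
    if not rows:
        raise QCTStiffError("VOI stage failed for every specimen")
    pd.DataFrame(rows).to_csv(outdir / "vbmd.csv", index=False)
    _record_failures(outdir, failures, "voi")


def stage_fem(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows, failures = [], []
    for sdir in _specdirs(outdir):
        sid = sdir.name
        try:
            image = CTImage.from_nifti(_require(sdir / "ct.nii.gz"))
            plane = ResectionPlane.from_json(_require(sdir / "plane.json"))
            models = _load_models(sdir)
            voi = VOIMask.from_nifti(_require(sdir / "voi.nii.gz"), cfg.voi_depth)
            t0 = time.perf_counter()
            results = fem_specimen(image, models, voi, plane, cfg)
            log.info("%s fem: %d methods in %.1fs", sid, len(results),
                     time.perf_counter() - t0)
            for method, r in results.items():
                rows.append({"specimen_id": sid, "method": method,
                             "F_N": r.reaction_force, "A_mm2": r.apparent_area,
                             "stress_MPa": r.apparent_stress,
                             "stiffness_MPa": r.apparent_stiffness})
        except QCTStiffError as exc:
            log.error("%s fem failed: %s", sid, exc)
            failures.append({"specimen_id": sid, "stage": "fem",
                             "error": str(exc)})
    if not rows:
        raise QCTStiffError("FEM stage failed for every specimen")
    pd.DataFrame(rows).to_csv(outdir / "stiffness.csv", index=False)
    _record_failures(outdir, failures, "fem")


def stage_agree(cfg: RunConfig, outdir: str | Path) -> None:
    from .agreement import cohort_agreement

    outdir = Path(outdir)
    vbmd = pd.read_csv(_require(outdir / "vbmd.csv"))
    vbmd = vbmd[vbmd.method != TRUTH_METHOD]
    stiff_path = outdir / "stiffness.csv"
    stiffness = None
    if stiff_path.exists():
        stiffness = pd.read_csv(stiff_path).rename(
            columns={"stiffness_MPa": "stiffness_mpa"})
    internal = [m for m in cfg.combinations if m in set(vbmd.method)]
    agr = cohort_agreement(vbmd, stiffness, internal_methods=internal)
    agr.to_json(outdir / "agreement.json")
    agr.to_frame().to_csv(outdir / "agreement.csv", index=False)


def _record_failures(outdir: Path, failures: list, stage: str) -> None:
    if failures:
        path = outdir / "failures.csv"
        df = pd.DataFrame(failures)
        if path.exists():
            df = pd.concat([pd.read_csv(path), df], ignore_index=True)
        df.to_csv(path, index=False)
        log.warning("%d specimen(s) failed during %s", len(failures), stage)


def _write_manifest(cfg: RunConfig, outdir: Path) -> None:
    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {"package": "qctstiff", "version": __version__,
                "config": cfg_dict,
                "config_sha256": hashlib.sha256(blob).hexdigest()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


STAGES = ("generate", "calibrate", "voi", "fem", "agree")


def run(cfg: RunConfig, outdir: str | Path) -> Path:
    """Run the full pipeline (all stages) into ``outdir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    outdir = Path(outdir)
    stage_generate(cfg, outdir)
    stage_calibrate(cfg, outdir)
    stage_voi(cfg, outdir)
    if cfg.with_fem:
        stage_fem(cfg, outdir)
    stage_agree(cfg, outdir)
    return outdir
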