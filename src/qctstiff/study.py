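"""Self-contained validation studies on synthetic data.

These are the computations behind the package's headline checks; both the
test suite and ``scripts/acceptance.py`` call them so the reported numbers
always come from a fresh run of the pipeline:

* :func:`cube_oracle` — homogeneous-cube compression with the closed-form
  answer (apparent stiffness = E when the Poisson ratio is zero), plus
  equilibrium/energy diagnostics and a mesh-refinement comparison.
* :func:`noiseless_recovery` — on a drift-free, noise-free specimen whose
  ground-truth HU/density law matches the reference table, every calibration
  route must recover the law to machine precision, and must keep recovering
  it when a global gain/offset drift is injected.
* :func:`recovery_study` — a noisy synthetic cohort: per-specimen VOI vBMD
  error against ground truth, the vBMD-stiffness regression, and
  Bland-Altman recovery of a deliberately injected calibration offset.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .calibrate import (apply_calibration, cortical_reference,
                        default_reference_table, fit_internal, fit_phantom,
                        sample_roi)
from .agreement import bland_altman, fit_regression
from .femstiff import (FEConfig, build_voi_mesh, density_to_modulus,
                       map_materials, run_fem, solve_compression,
                       extract_surface, tetrahedralize)
from .image import CTImage, DensityImage
from .pipeline import RunConfig, calibrate_specimen, fem_specimen, measure_specimen
from .synthdata import (CORTICAL, TRABECULAR, CohortDistribution, ScannerModel,
                        SpecimenSpec, cohort, generate_specimen)
from .voi import VOIMask


# ---------------------------------------------------------------------------
# FE oracle

def make_cube_voi(edge_mm: float = 10.0, spacing: float = 1.0) -> VOIMask:
    n = int(round(edge_mm / spacing))
    return VOIMask(np.ones((n, n, n), bool), (spacing,) * 3,
                   (spacing / 2,) * 3, depth=edge_mm)


def cube_oracle(edge_mm: float = 10.0, modulus_mpa: float = 5000.0,
                strain: float = 0.01, max_edge: float = 1.5,
                refine: bool = True) -> dict:
    """Compress a homogeneous cube with rigid end plates at nu = 0.

    The uniform uniaxial state is exactly representable by linear tets, so
    the apparent stiffness must equal the prescribed modulus.  Returns the
    stiffness, the equilibrium/energy residuals, and the relative change
    under one max-edge halving.
    """
    voi = make_cube_voi(edge_mm)
    # density whose power-law modulus equals modulus_mpa exactly
    rho = (modulus_mpa / 12486.0) ** (1.0 / 1.16) * 1000.0
    density = DensityImage(np.full(voi.shape, rho), voi.spacing, voi.origin,
                           calibration="uniform")

    def solve(me: float):
        cfg = FEConfig(max_edge=me, poisson_ratio=0.0, strain=strain)
        tet = build_voi_mesh(voi, None, cfg)
        return run_fem(density, voi, cfg, tet=tet)

    r1 = solve(max_edge)
    out = {
        "stiffness_mpa": r1.apparent_stiffness,
        "reaction_force_n": r1.reaction_force,
        "apparent_area_mm2": r1.apparent_area,
        "applied_displacement_mm": strain * edge_mm,
        "equilibrium_residual": r1.equilibrium_residual,
        "energy_balance": r1.energy_balance,
        "n_tets": r1.n_tets,
    }
    if refine:
        r2 = solve(max_edge / 2.0)
        out["refined_stiffness_mpa"] = r2.apparent_stiffness
        out["refinement_rel_change"] = abs(
            r2.apparent_stiffness - r1.apparent_stiffness) / r1.apparent_stiffness
    return out


# ---------------------------------------------------------------------------
# calibration recovery

def _small_spec() -> SpecimenSpec:
    return SpecimenSpec(head_radius=12.0, cortical_thickness=2.0,
                        grid_shape=(48, 48, 56), spacing=(1.0, 1.0, 1.0),
                        muscle_thickness=6.0, adipose_thickness=5.0)


def noiseless_recovery(spec: SpecimenSpec | None = None) -> dict:
    """Exact-recovery errors of every calibration route (no noise).

    Fits phantom + AAdC/AAdCM/ACM on an identity-scanner specimen and on a
    gain/offset-drifted copy; reports the worst relative error of the
    recovered law against the ground-truth law, and the worst voxelwise
    relative disagreement of calibrated densities between the two scans
    (drift cancellation).
    """
    spec = spec or _small_spec()
    cfg = RunConfig(n_specimens=1, spec=spec, cortical_mode="max",
                    with_fem=False)
    truth_slope, truth_intercept = spec.density_hu_slope, spec.density_hu_intercept

    img0, truth = generate_specimen(spec, ScannerModel())
    img1, _ = generate_specimen(spec, ScannerModel(gain=1.07, offset=35.0))

    out = {"max_slope_rel_err": 0.0, "max_intercept_err_rel": 0.0,
           "max_drift_rel_err": 0.0}
    models0, _ = calibrate_specimen(img0, truth.tissue_labels, cfg,
                                    spec.phantom_rod_densities)
    models1, _ = calibrate_specimen(img1, truth.tissue_labels, cfg,
                                    spec.phantom_rod_densities)
    scale = max(abs(truth_intercept), abs(truth_slope) * 1000.0)
    bone = truth.tissue_labels >= TRABECULAR
    for method, m0 in models0.items():
        out["max_slope_rel_err"] = max(
            out["max_slope_rel_err"], abs(m0.slope - truth_slope) / truth_slope)
        out["max_intercept_err_rel"] = max(
            out["max_intercept_err_rel"], abs(m0.intercept - truth_intercept) / scale)
        d0 = apply_calibration(img0, m0).voxels[bone]
        d1 = apply_calibration(img1, models1[method]).voxels[bone]
        rel = np.max(np.abs(d1 - d0) / np.maximum(np.abs(d0), 1.0))
        out["max_drift_rel_err"] = max(out["max_drift_rel_err"], float(rel))
    return out


# ---------------------------------------------------------------------------
# noisy cohort study

def recovery_study(n: int = 20, seed: int = 0,
                   spec: SpecimenSpec | None = None,
                   distribution: CohortDistribution | None = None,
                   injected_offset: float = 10.0,
                   with_fem: bool = True) -> dict:
    """Noisy synthetic-cohort recovery study.

    Conditions: per-specimen scanner gain in [0.95, 1.05], offset in
    [-20, 20] HU, HU noise SD 10; between-specimen trabecular density scale
    0.75-1.25.  Reports:

    * worst per-specimen relative error of internally calibrated VOI vBMD
      against the ground-truth mean over the same voxels (all combinations);
    * vBMD-vs-stiffness regression (slope, r^2) for the phantom and ACM arms;
    * Bland-Altman bias of the ACM arm after injecting a constant
      ``injected_offset`` mg/cm^3 into the internal calibration, which the
      analysis must recover as a bias of ~``injected_offset`` (the base
      ACM-vs-phantom bias on this synthetic cohort is ~0).
    """
    spec = spec or _small_spec()
    distribution = distribution or CohortDistribution(
        gain_range=(0.95, 1.05), offset_range=(-20.0, 20.0), noise_sd=10.0,
        density_scale_range=(0.75, 1.25))
    cfg = RunConfig(n_specimens=n, seed=seed, spec=spec,
                    distribution=distribution, with_fem=with_fem)

    vbmd_rows, stiff_rows = [], []
    for img, truth, info in cohort(spec, n, distribution, seed):
        sid = info["specimen_id"]
        models, _ = calibrate_specimen(img, truth.tissue_labels, cfg,
                                       spec.phantom_rod_densities)
        voi, vbmd = measure_specimen(img, models, truth.resection_plane, cfg,
                                     gt_density=truth.density_field)
        for m, v in vbmd.items():
            vbmd_rows.append({"specimen_id": sid, "method": m, "vbmd": v})
        if with_fem:
            for m, r in fem_specimen(img, {k: models[k] for k in ("PHANTOM", "ACM")},
                                     voi, truth.resection_plane, cfg).items():
                stiff_rows.append({"specimen_id": sid, "method": m,
                                   "stiffness_mpa": r.apparent_stiffness})

    vb = pd.DataFrame(vbmd_rows).pivot(index="specimen_id", columns="method",
                                       values="vbmd")
    internal = [m for m in ("AAdC", "AAdCM", "ACM") if m in vb.columns]
    rel_err = (vb[internal].sub(vb["TRUTH"], axis=0)).abs().div(vb["TRUTH"], axis=0)
    out = {
        "n": n,
        "max_vbmd_rel_err_pct": float(rel_err.max().max() * 100.0),
        "mean_vbmd_rel_err_pct": float(rel_err.mean().mean() * 100.0),
    }

    ba = bland_altman(vb["PHANTOM"], vb["ACM"] + injected_offset)
    out["injected_offset_mg_cm3"] = injected_offset
    out["recovered_bias_mg_cm3"] = ba.mean_difference
    out["base_bias_mg_cm3"] = ba.mean_difference - injected_offset \
        if injected_offset else ba.mean_difference

    if with_fem:
        st = pd.DataFrame(stiff_rows).pivot(index="specimen_id",
                                            columns="method",
                                            values="stiffness_mpa")
        st = st.reindex(vb.index)
        for method in ("PHANTOM", "ACM"):
            reg = fit_regression(vb[method], st[method])
            out[f"{method.lower()}_vbmd_stiffness_slope"] = reg.slope
            out[f"{method.lower()}_vbmd_stiffness_r2"] = reg.r_squared
        out["stiffness_tables"] = st
    out["vbmd_tables"] = vb
    return out
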