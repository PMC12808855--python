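"""Cohort-level agreement between internal and phantom calibration.

Runs a small synthetic cohort end to end (without FE, for speed), then
summarizes each internal method against the phantom reference with linear
regression and Bland-Altman statistics.
"""

import pandas as pd

from qctstiff import CohortDistribution, SpecimenSpec, cohort
from qctstiff.agreement import cohort_agreement
from qctstiff.pipeline import RunConfig, calibrate_specimen, measure_specimen

spec = SpecimenSpec(head_radius=12.0, cortical_thickness=2.0,
                    grid_shape=(48, 48, 56), spacing=(1.0, 1.0, 1.0),
                    muscle_thickness=6.0, adipose_thickness=5.0)
dist = CohortDistribution(gain_range=(0.95, 1.05), offset_range=(-20, 20),
                          noise_sd=10.0, density_scale_range=(0.75, 1.25))
cfg = RunConfig(n_specimens=10, spec=spec, distribution=dist, with_fem=False)

rows = []
for image, truth, info in cohort(spec, cfg.n_specimens, dist, seed=5):
    models, _ = calibrate_specimen(image, truth.tissue_labels, cfg,
                                   spec.phantom_rod_densities)
    _, vbmd = measure_specimen(image, models, truth.resection_plane, cfg)
    rows += [{"specimen_id": info["specimen_id"], "method": m, "vbmd": v}
             for m, v in vbmd.items()]

agr = cohort_agreement(pd.DataFrame(rows))
print(f"{'pair':>16} {'bias':>8} {'LoA':>20} {'%err':>7} {'r^2':>7}")
for rep in agr.reports:
    ba, reg = rep.bland_altman, rep.regression
    print(f"PHANTOM vs {rep.method_pair[1]:>5} {ba.mean_difference:8.3f} "
          f"[{ba.lower_limit:8.3f}, {ba.upper_limit:8.3f}] "
          f"{ba.percent_error:7.3f} {reg.r_squared:7.4f}")
# On this synthetic cohort the internal methods agree with the phantom to a
# fraction of a mg/cm^3: the generator has no systematic tissue-HU shift, so
# any bias is purely noise-driven.
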