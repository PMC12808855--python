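# Methods

## Scope and model

`qctstiff` quantifies how the choice of CT density calibration — in-scan
K₂HPO₄ rod phantom versus internal referent tissues — propagates to the
volumetric BMD and finite-element apparent stiffness of the 10 mm of bone
below the humeral anatomic-neck resection plane.  Because no public dataset
couples shoulder CTs with an in-scan phantom and a defined resection plane,
the pipeline is validated on synthetic cohorts with known ground truth; the
library applies unchanged to real NIfTI/MetaImage volumes given ROI masks
and a resection-plane file.

## Synthetic specimens

A specimen is a hemispherical head (default radius 18 mm; desk-scale tests
use 12 mm) on a truncated-cone metaphysis, with:

* a cortical shell (default 2.5 mm) at a nominal 1200 HU;
* a trabecular interior with a radial density gradient (default
  100–400 mg K₂HPO₄/cm³, densest at the cortex) so the VOI is spatially
  heterogeneous;
* muscle (40 HU) and subcutaneous adipose (−60 HU) layers, air at −1000 HU —
  standard radiology reference values;
* a row of cylindrical K₂HPO₄ rods below the anatomy (defaults 0–600
  mg/cm³, five rods; rod count/densities are configuration, since real
  phantom models differ).

Inside bone and rods, true density and ideal HU are linked by a configurable
linear law (default ρ = 0.75·HU mg/cm³), so any correct calibration must
recover that law exactly in the noiseless case.  A scanner model then
applies `HU_obs = gain·HU_ideal + offset + N(0, σ)`.  Defaults for cohorts:
gain 0.95–1.05, offset ±20 HU, σ = 10 HU per scan.  Cohorts additionally
scale each specimen's trabecular density range by a factor drawn from
0.75–1.25, emulating between-donor BMD variation; without it a synthetic
cohort would have no between-specimen vBMD variance and regression
statistics would be meaningless.

What the generator does **not** emulate: beam hardening (the clinical
protocol mitigates it by placing ROIs at the VOI level rather than modelling
it), partial-volume blur at tissue boundaries, anatomical shape variation,
cadaveric muscle-HU depression (representable via the configurable muscle
mean HU), and pathological (osteoarthritic) density patterns.  Passing
recovery tests therefore demonstrate the *pipeline's* correctness — that
calibration cancels affine drift, that the VOI and FE stages measure what
they claim — not the clinical accuracy of internal calibration on real
shoulders, which depends on exactly the tissue-HU deviations the generator
idealizes away.

## Calibration

Both routes fit HU against reference density by ordinary least squares
(HU-on-density, inverted to `ρ = slope·HU + intercept`), so phantom and
internal fits on identical point sets give identical models.

* **Phantom (ROD):** rod mean HU vs known rod densities.  An optional water
  correction subtracts `(water-equivalent density − 1000)` mg/cm³ from each
  rod's density axis; the vendor's exact correction formula is proprietary,
  so this documented approximation is off by default.
* **Internal:** air/adipose/muscle ROI means plus a cortical reference from
  bone voxels in the 1000–1500 HU window, in combinations AAdC, AAdCM, ACM.
  The reference equivalent densities assigned to tissues are
  *implementation-chosen* configuration (the published internal-calibration
  tooling derives them from attenuation physics it does not print); defaults
  lie on the synthetic ground-truth law so that recovery is exactly
  checkable.

**Cortical reference rule.** The clinical rule takes the *highest* HU in the
window.  On synthetic images whose cortical compartment is nominally uniform
with i.i.d. Gaussian noise, that windowed maximum is an extreme-value
statistic whose bias grows with the size of the cortical region (≈ +4σ at
test sizes) — an artifact of the idealized noise model, not a property of
the method, since real cortical HU heterogeneity is what the max is meant to
track.  Both rules are implemented (`mode="max"` / `mode="mean"`);
`cortical_reference` defaults to the literal max rule, while the synthetic
cohort pipeline defaults to the windowed mean, the unbiased estimator of the
same reference point under the generator's assumptions.

## VOI

Bone is segmented at HU > 225; the largest 26-connected component is kept
and interior holes are filled (the low-density trabecular center falls below
the threshold by design).  The VOI is the Boolean intersection of that mask
with the slab between the resection plane and its parallel offset 10 mm
along the distal normal, using a voxel-center membership test (no
partial-volume weighting; deterministic and unbiased at the sizes used).
The slab's lateral extent defaults to 200 mm — larger than any bone
cross-section, so the bone boundary governs laterally.  One VOI per specimen
is shared by every calibration method; between-method differences are purely
calibration differences.

## Finite-element model

* **Meshing.** The VOI lattice is subdivided until the longest element edge
  (the cell face diagonal) is ≤ the 1.5 mm target, then each cell is split
  into five tetrahedra with parity-alternating diagonals so faces conform.
  The boundary triangulation coincides with the voxel surface: watertight by
  construction, zero geometric deviation from the mask, exact volume
  conservation.  This trades the smooth remeshed surfaces of commercial
  tools for determinism and exactness; at 1 mm voxels the staircase boundary
  perturbs the apparent area by less than the voxel-membership uncertainty
  already present in the VOI.  A Delaunay-with-winding-number fallback
  handles externally supplied watertight surfaces.
* **Materials.** Element density is the mean of the trilinearly interpolated
  density image at the 4-point Gauss rule (an approximation of Bonemat-style
  element integration; the rule is configurable).  One power law
  `E = 12 486·ρ^1.16` MPa (ρ in g K₂HPO₄/cm³) is applied across the entire
  density range — no cortical/trabecular split.  Calibrated densities at or
  below zero (possible under noise) are floored at 0.001 g/cm³ (≈ 4.1 MPa),
  keeping the law real-valued and the stiffness matrix positive definite.
* **Boundary conditions.** Small-strain isotropic linear elasticity with
  constant-strain tetrahedra; the distal surface is fully fixed and every
  proximal node shares one prescribed translation along the slab normal
  (rigid coupling with rotations suppressed — for this axial, symmetric load
  the suppressed rotations carry no moment).  Prescribed displacement is
  `strain × slab depth` (0.1 mm at 1% over 10 mm).  Poisson's ratio defaults
  to 0.3 (conventional for QCT-FE bone; not dictated by the stiffness
  definition) and is set to 0 in closed-form oracle tests, where the uniform
  uniaxial state is exactly representable and the apparent stiffness must
  equal the material modulus to solver precision.
* **Outputs.** Reaction force is the magnitude of the summed distal nodal
  reactions along the load axis (signed-axis sum; for this axial problem it
  equals the resultant magnitude).  Apparent area is the mean of the
  proximal and distal boundary-face areas; apparent stress = F/A; apparent
  stiffness = stress/strain.  Direct sparse solve; residual, global
  force-balance, and energy-balance diagnostics are recorded on every
  result and asserted in tests (≤ 10⁻⁶ relative).

## Agreement statistics

Differences are oriented internal − phantom; limits of agreement use the
fixed 1.96 multiplier; percent error is 100·bias / mean(reference series)
(the reported tables are consistent with a cohort-mean denominator; the
convention is documented rather than asserted).  Heteroscedasticity is
probed by regressing |differences| on pairwise means.  Shapiro–Wilk and
maximum Cook's distance are reported for every regression and never used to
remove observations.  Exact fits (zero residuals) report Shapiro p = 1 and a
slope-vs-unity p of 1 when the slope is 1 — the degenerate limits of those
tests.

## Problem sizes and determinism

Tests and the acceptance study run desk-scale specimens (12 mm head,
48×48×56 grid at 1 mm; VOIs of ~4 000 voxels → ~19 000 tets) and cohorts of
n = 20; the generator defaults target 128³ grids.  These sizes were chosen
so the full suite exercises every stage, including ~80 FE solves, in a few
minutes while leaving all statistical conclusions unchanged — the recovery
errors scale with noise/√(VOI voxels), which desk-scale VOIs already make
sub-percent.  Every random draw flows from explicit seeds
(`numpy.random.default_rng`); a cohort's per-specimen seeds derive from the
master seed, so identical configuration + seed reproduces byte-identical
CSV outputs, and the run manifest records the configuration hash.

## Known limitations

* The FE model estimates an apparent, linear, isotropic stiffness under one
  axial load case; no implant contact, shear, anisotropy, or failure.
* The staircase voxel surface is not the 0.15 mm-tolerance remeshed surface
  of commercial pipelines; mesh-convergence of the apparent stiffness is
  verified on oracle geometry, not proven for arbitrary anatomies.
* Internal-calibration reference densities are configuration; absolute vBMD
  accuracy on real scanners requires site-specific values.
* Resection planes are inputs (ground truth for synthetic data, a JSON file
  for real data); anatomic-neck detection is out of scope.
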