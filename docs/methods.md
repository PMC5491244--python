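# Methods

## Scope and design

`bnctdose` reimplements a multi-field BNCT planning comparison as a
self-contained pipeline. Two stand-ins replace components that cannot
be shipped: a parametric four-component beam model replaces Monte Carlo
neutron/photon transport, and seeded synthetic head phantoms replace
patient simulation CTs. Everything downstream of those stand-ins — the
DRSF/RBE dose weighting, field-weight balancing, prescription
normalization, DVH metrics and the cohort statistics — follows the
clinical protocol directly.

## Beam model

Each field contributes four physical dose-rate components, evaluated at
the voxel's water-equivalent (radiological) depth `d` along the beam:

* thermal neutron and boron capture: `A (exp(-d/L_slow) − exp(-d/L_build))`
  — the thermal fluence builds up over the first centimetres as
  epithermal neutrons moderate, then decays. Both components are
  proportional to the thermal fluence, so they share the shape;
* fast neutron: `A exp(-d/1.6 cm)` — concentrated near the surface;
* photon: build-up/decay pair with lengths 0.9 / 5.0 cm. The 5.0 cm
  decay is the longest in the model (photons are the most penetrating
  component) while still attenuating below 10⁻³ of peak by 40 cm depth,
  the depth at which all curves are treated as fully extinguished.

Defaults (Gy/min at the 1.2 MW, 1.28×10⁹ n·cm⁻²·s⁻¹ reference
operating point; `src/bnctdose/data/thor_default.yaml`):

| parameter | value | why |
|---|---|---|
| amplitudes (thermal/fast/photon/B10) | 0.060 / 0.080 / 0.140 / 0.360 | relative mix gives a boron-dominated tumor dose with a realistic fast/photon skin contribution; the overall scale is set so a default 4F plan's beam-on time lands in the published 40–75 min band (~52 min). The advantage depth is invariant under this uniform rescaling. |
| `neutron_buildup_cm` | 1.0 | thermal build-up over the first ~2 cm |
| `neutron_decay_cm` | 4.0211 (calibrated) | the one free shape parameter; root-found so the advantage depth is 8.5 cm (below) |
| `fast_decay_cm` / photon lengths | 1.6 / 0.9, 5.0 | fixed shape constants, see above |
| `collimator_diameter_cm`, `penumbra_cm` | 14, 0.5 | flat field with an error-function penumbra whose half-value sits exactly on the 7 cm field edge |
| `neutron_lateral_half_width_cm` | 4.5 | in-phantom transverse falloff of the neutron fluence (below) |
| `reference_boron_ppm` | 25 | assumed normal-tissue ¹⁰B concentration for BPA; the boron dose is linear in local concentration, so this constant only fixes the absolute dose-rate scale |

The boron curve is stored per reference concentration; a two-compartment
boron map (T/N = 3.5 × reference inside the CTV, reference elsewhere in
the body) scales it per voxel. The CTV *mask*, not the material label,
selects the tumor CBE (3.8 vs 1.3): target voxels are tumor
radiobiologically even where their density is brain-like.

### Advantage-depth calibration

The advantage depth (AD) is the only transport-level observable
published for the beam: the largest depth at which the RBE-weighted
tumor dose equals the maximum RBE-weighted normal-tissue dose along the
central axis, 8.5 cm at T/N 3.5. `compute_advantage_depth` locates it
by a 0.01 cm grid scan plus bisection; `calibrate_beam_model`
root-finds `neutron_decay_cm` (shared by the thermal and boron curves)
to hit a target AD, and the shipped default carries the pre-calibrated
value. Useful invariants: the AD is unchanged under uniform rescaling
of all amplitudes (a crossing point of two jointly scaled curves), and
non-decreasing in T/N (more tumor boron can only deepen the crossing).

### Transverse fluence falloff

A purely geometric flat profile is wrong for multi-field comparisons on
a head smaller than the field: every field then deposits its near-peak
dose over the whole facing surface cap, adjacent fields' caps overlap
at roughly twice the per-field normal-tissue maximum, and adding fields
*worsens* normal-tissue sparing — the opposite of the published
behaviour. Physically, the thermal fluence inside a narrow head falls
off away from the beam axis because moderated neutrons leak through the
nearby lateral surfaces; Monte Carlo transport captures this, a 1-D
depth kernel does not. The model therefore multiplies the
neutron-driven components (thermal, fast, boron) by a Gaussian in
off-axis distance with half-value 4.5 cm, leaving the photon component
with the collimator profile only. The field-count orderings reproduced
by the cohort are robust over half-widths of at least 3.5–7 cm; 4.5 cm
also places the metric magnitudes near the published means. The factor
is 1 on axis, so the AD calibration is unaffected.

## Dose computation

Radiological depth is the path integral of water-equivalent density
(air 0, soft tissue/brain/tumor 1.0, bone 1.4 — a deliberate
simplification of a full tissue library) from the body entry surface.
Depth maps are computed by resampling the density grid into a
beam-aligned frame (trilinear), accumulating a midpoint-rule cumulative
sum along the beam axis, and resampling back; because air carries zero
density, integrating from the grid edge equals integrating from the
body surface for a convex phantom. Beams are parallel (non-divergent)
and coplanar-axial; material boundaries sit at midpoints between voxel
centres under the interpolation convention, so surfaces are effectively
resolved to half a voxel. A slower per-voxel ray-marching routine
(`radiological_depth`) provides an independent reference path.

RBE weighting is linear in every component and in beam-on time, so
per-field RBE rate maps (Gy-Eq/min at unit weight) are computed once
per angle and superposed; a provenance flag refuses double application
of the DRSF adjustment.

## Planning

* Standard angle sets: 1F {0°}, 2F {90°, 270°}, 3F {60°, 180°, 300°},
  4F {0°, 90°, 180°, 270°}; the single field exists only to demonstrate
  the futility of one port for a target deeper than the AD.
* Weight balancing automates the protocol's manual rule ("per-direction
  maximal normal-tissue dose within 10%"): fixed-point iteration
  `w ← w / NTmax(w)`, normalized to mean 1, capped at 100 iterations
  (for fixed per-field maps one step equalizes exactly; the cap is a
  guard). The per-field figure is each field's *own* maximal dose
  contribution over normal tissue, and "normal tissue" is body minus
  CTV (configurable by passing a different mask).
* Prescription normalization: total beam-on time = 20 Gy-Eq divided by
  the per-minute dose exceeded by exactly 80% of CTV voxels — the
  exact linearly interpolated empirical quantile, i.e. the continuum
  limit of DVH inversion. This keeps D80 = prescription to ~0.01%,
  surviving re-inversion through a 0.05 Gy-Eq binned DVH within 0.1%.
  Beam-on time splits across fields proportionally to weight.

## Evaluation

Cumulative DVHs store the exact voxel-counting survival fraction at
0.05 Gy-Eq bin edges; Dx lookups linearly interpolate the inverse
curve. In metric reports, D95/D5 are clamped into [Dmin, Dmax]: for a
(near-)uniform dose the half-bin interpolation error would otherwise
place D95 below Dmin and break the ordering chain
Dmin ≤ D95 ≤ Dmean ≤ D5 ≤ Dmax. HI = D5/D95; integral dose =
mean dose × volume (Gy-Eq·L); therapeutic gain = CTVmin/NTmax.
Organ-at-risk tolerance comparisons are strict (`Dmax < limit`; a dose
exactly at the limit fails), and a structure missing from the set is
reported absent rather than skipped. Deepest tumor depth per angle uses
geometric (not radiological) distance from the body surface, matching
depth as measured on CT images.

## Synthetic phantoms

Nested axis-aligned ellipsoids on a 2 mm isotropic LPS grid (axial
plane = slice plane; 0° = anterior, 90° = left): soft-tissue scalp
(0.5 cm), bone shell (0.7 cm), interior soft tissue, brain ellipsoid,
and a brainstem CTV ellipsoid offset 1.28 cm posterior of centre.
Optic-nerve surrogates are antero-posterior cylinders, the circle of
Willis a small torus at the skull base. Per-phantom variation applies
truncated-Gaussian (±2.5 σ) scale factors — a common head scale plus
per-axis factors (σ 2% / 1%) — and a small CTV position jitter.

Defaults were tuned to two population targets only: per-angle deepest
CTV depths inside the published per-angle ranges (e.g. ~11.7 cm
anterior, ~9.2 cm posterior, ~9.4 cm lateral) for every seed, and
structure volumes near the published means (normal brain ~1.1 L, optic
nerves ~1.5 cm³, circle of Willis ~1.1 cm³). Anatomical realism beyond
these statistics is a non-goal: there is no CSF, no ventricles, no real
skull-base geometry, ellipsoids are axis-aligned, and the left/right
symmetry is only weakly broken. Consequences: cohort variances are
smaller than clinical ones (the published SDs reflect real anatomical
heterogeneity), balanced weights sit close to 1, and per-patient cells
of the published tables are not reproducible — only protocol-level
numbers and field-count trends are meaningful, which is what the tests
assert.

A synthetic-CT pair of helpers (`synthesize_hu` /`assign_materials`)
emulates the imaging step: per-material mean HU (air −1000, soft 40,
bone 700, brain 35, tumor 38) plus Gaussian noise, and threshold
classification (−500 / 36.5 / 39 / 300 HU) that inverts the noise-free
map exactly.

## Cohort statistics

The driver runs phantom seeds `base_seed + i` through the full pipeline
for each plan type (deterministic given the base seed) and summarises
each metric as mean ± sample SD (n−1) per plan type. One-way ANOVA is
computed directly (between/within mean squares); pairwise comparisons
use Tukey's HSD via the studentized range on the pooled within-group
variance — the published report does not name its post-hoc procedure,
so no claim is made of matching its pairwise p values. Both statistics
are cross-checked against independent reference implementations in the
test suite. Default cohort size is 12 phantoms at 2 mm voxels; a full
2F/3F/4F cohort runs in well under a minute on one CPU.

## Numerical choices and degenerate inputs

* Bisection tolerances: AD to 0.01 cm; calibration to 0.05 cm of target.
* Equal build-up and decay lengths make the thermal/boron curves
  identically zero (degenerate difference); tiny negative round-off in
  the curve differences is clamped to zero.
* An AD is refused explicitly (`AdvantageDepthUndefinedError`) when the
  tumor curve never reaches the normal-tissue maximum.
* A field that misses the body yields an all-zero map with a warning;
  empty masks, non-positive spacings, non-monotone HU thresholds, a CTV
  leaving the brain, zero CTV dose at normalization, and mismatched
  grids all raise immediately.
* Axis-aligned beam directions are snapped exactly (1e-16 trig residue
  would otherwise push boundary samples outside the grid during
  resampling).

## Known limitations

No Monte Carlo transport: spectra, angular flux, in-air scatter and
KERMA factors are absorbed into four calibrated curves, valid only near
the calibrated operating point. Parallel beams ignore divergence. The
5-material tissue model and the 1.4 bone factor are coarse. Boron
pharmacokinetics are static two-compartment. Fixed RBE/CBE only — no
TCP/NTCP or dose-rate effects. The phantom population undersamples real
anatomical variance, so ANOVA p values characterize the synthetic
cohort, not patients.
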