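# bnctdose

Dosimetric feasibility pipeline for multi-field boron neutron capture
therapy (BNCT) of deep-seated brainstem tumors (diffuse intrinsic
pontine glioma, DIPG), built for treatment-planning researchers who
want to rerun and stress-test the 2-field / 3-field / 4-field
comparison on synthetic anatomy.

DIPG infiltrates the pons and cannot be resected; conventional
radiotherapy is capped by brainstem tolerance. BNCT loads tumor cells
with a ¹⁰B carrier (BPA, tumor/normal concentration ratio T/N = 3.5)
and irradiates with an epithermal neutron beam; the ¹⁰B(n,α)⁷Li capture
reaction deposits short-range high-LET dose preferentially in tumor.
The catch is depth: beyond the beam's *advantage depth* (AD) — the
depth at which the tumor dose falls to the maximum normal-tissue dose
along the beam, 8.5 cm here — a single field gives no therapeutic
benefit, and a brainstem target sits 8.3–12.8 cm from the surface
depending on beam angle. Multiple crossed fields are therefore the only
non-invasive option, and the question is how much the field count buys.

## Model

Physical dose is bookkept as four components with closed-form
central-axis depth-dose curves (thermal-neutron, fast-neutron, photon,
and boron capture; the boron curve scales linearly with local ¹⁰B
concentration). Each computed component D is first normalized by its
measured dose-rate scaling factor,

    D_adj(c) = DRSF(c) · D(c),   DRSF = 0.64 / 1.39 / 0.96 / 0.65
                                 (thermal / fast / photon / B-10)

and the biologically weighted dose (Gy-Eq) of a voxel is

    D_RBE = RBE_th·D_adj(th) + RBE_fast·D_adj(fast)
          + RBE_ph·D_adj(ph) + CBE(tissue)·(c_B/c_ref)·D_adj(B10)

with RBE 3.2 for the high-LET neutron components, 0.5 for photons, and
a tissue-dependent boron CBE of 3.8 (tumor) / 1.3 (brain). The shared
slow-decay length of the thermal/boron curves is calibrated so the
model's AD is exactly 8.5 cm; neutron-driven components also fall off
transversely inside the head (leakage), which is what lets additional
fields spread out, rather than stack, the near-surface normal-tissue
peaks.

Plans follow the published protocol: standard coplanar angle sets
(2F = 90°/270°, 3F = 60°/180°/300°, 4F = 0°/90°/180°/270°, 14-cm
collimator), field weights balanced until each field's maximal
normal-tissue dose contribution agrees within 10%, prescription
normalized to 20 Gy-Eq covering 80% of the CTV, and evaluation by
cumulative DVH: CTV min/max/mean, D95, homogeneity index HI = D5/D95,
therapeutic gain CTVmin/NTmax, integral dose (mean dose × volume,
Gy-Eq·L), and organ-at-risk maxima checked against NB < 13, ON < 10,
CW < 12 Gy-Eq.

Patient CTs are replaced by a seeded generator of nested-ellipsoid head
phantoms (scalp / skull / brain / brainstem CTV, optic-nerve and
circle-of-Willis surrogates) whose per-angle deepest-CTV depths and
structure volumes reproduce the published population statistics. See
`docs/methods.md` for parameter-level detail and limitations.

## Worked example

```
$ bnctdose plan --fields 4 --seed 1 --out out/plan4f
4F plan: total 53.3 min, gain 2.84, NB Dmax 6.04 Gy-Eq
```

This generates the seed-1 phantom, traces the four fields, balances
weights (all 1.0 here — the phantom is nearly symmetric, so the
per-field normal-tissue maxima already agree within 10%), and scales
beam-on time so that 80% of the CTV receives 20 Gy-Eq. `out/plan4f/`
then holds the dose map (`dose.nrrd`), DVH curves (`dvh_ctv.csv`,
`dvh_nb.csv`) and the full metric bundle (`plan.json`), e.g.:

| quantity | value | meaning |
|---|---|---|
| total beam-on time | 53.3 min | four 13.3-min fields delivered sequentially |
| CTV min / mean / max | 18.6 / 20.9 / 23.2 Gy-Eq | target coverage around the 20 Gy-Eq prescription |
| HI | 1.16 | D5/D95 dose homogeneity inside the CTV |
| gain (CTVmin/NTmax) | 2.84 | every tumor voxel gets ≥ 2.8× the hottest normal-tissue voxel |
| NB Dmax | 6.04 Gy-Eq | well under the 13 Gy-Eq normal-brain tolerance |

The cohort driver reruns the full design (12 seeded phantoms × plan
types) and emits per-plan and mean ± SD summary tables with one-way
ANOVA across plan types:

```
$ bnctdose cohort --n 12 --seed 1 --out out/cohort
gain: 2F 1.92±0.05, 3F 2.41±0.09, 4F 2.87±0.05
nb_dmax: 2F 8.42±0.27, 3F 6.68±0.26, 4F 6.03±0.14
total_minutes: 2F 46.03±2.11, 3F 51.48±2.26, 4F 51.64±2.30
```

The qualitative conclusion of the study design survives on synthetic
anatomy: therapeutic gain rises and the maximal normal-brain dose falls
monotonically from two to four fields, at essentially constant beam-on
time, while a single field (gain < 1 for a target deeper than the AD)
is futile.

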