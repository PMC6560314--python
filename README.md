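# brachyplan

Treatment-planning and QA toolkit for **template-guided ¹²⁵I seed
brachytherapy**, built around synthetic CT-like phantoms.

In low-dose-rate seed brachytherapy, small sealed ¹²⁵I sources
(3.0 × 0.5 mm) are implanted permanently in a tumor through parallel
needles guided by a coplanar template. Treatment quality hinges on two
things this package models end to end:

1. **Dosimetry** — will the planned seed arrangement cover the target?
2. **Positioning** — were the template, needles, and seeds actually placed
   where the plan said, and what did any deviation cost dosimetrically?

It is aimed at medical-physics researchers prototyping planning and QA
algorithms who need a fully synthetic, reproducible test bed rather than
clinical DICOM data.

## What's inside

| module      | contents |
|-------------|----------|
| `geometry`  | template/needle models, template poses, rigid transforms, slant angle θ, the vector-sum positioning error e_E |
| `tg43`      | TG-43 1-D dose engine for ¹²⁵I point sources, decay integration, dose-grid superposition |
| `planning`  | first-needle selection, greedy constraint-driven seed placement with source-strength selection |
| `dosimetry` | cumulative DVH, D_x / V_x, CI, HI, mean ± sd, t-tests, plan comparison reports |
| `phantom`   | synthetic CT-like phantoms (body, ellipsoidal tumor, ribs, markers, needles, seeds) with PSF-blurred partial-volume rendering, plus threshold/connected-component object detection and matching |
| `qa`        | end-to-end workflows: positioning simulation, error-validation Monte Carlo, implant QA |
| `published` | packaged reference-table values and their recomputation |

## The model in brief

Dose around a seed follows the AAPM TG-43 1-D formalism,

```
Ḋ(r) = S_K · Λ · (r₀/r)² · g(r) · φ_an(r),     r₀ = 1 cm,
```

with air-kerma strength S_K (U), dose-rate constant Λ (cGy·h⁻¹·U⁻¹),
radial dose function g(r) and anisotropy factor φ_an(r). A permanent
implant accumulates `D = Ḋ₀·τ·(1 − e^(−t/τ))`, τ = T½/ln 2
(T½ = 59.4 d for ¹²⁵I). Plans are judged by the standard three-metric
prescription — V100 ≥ 90 %, V150 ≤ 50 %, V200 ≤ 20 % — plus

```
CI = (V_T,ref / V_T) · (V_T,ref / V_ref)        (conformity index)
HI = (D₂ − D₉₈) / D_ref × 100 %                 (homogeneity index)
```

and positioning is judged by the Euclidean error between planned and
achieved points,
`e_E = √((x_P−x_Q)² + (y_P−y_Q)² + (z_P−z_Q)²)`,
and by the template slant angle (the acute angle between the first-needle
direction and the image vertical axis).

See `docs/methods.md` for assumptions, parameter defaults, and the
synthetic-phantom model.

## Worked example

Plan a 1-cm spherical target through an 11 × 11, 5-mm coplanar template,
then implant the reference six-seed case with 0.43 mm placement noise and
run implant QA:

```python
import numpy as np
from brachyplan import qa, phantom, planning
from brachyplan.tg43 import GridSpec
from brachyplan.dosimetry import StructureMask
from brachyplan.geometry import TemplatePose

ax = np.arange(40.0)
gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
tumor = StructureMask(GridSpec((0, 0, 0), (1, 1, 1), (40, 40, 40)),
                      (gx-20)**2 + (gy-20)**2 + (gz-20)**2 <= 25.0)
pose = TemplatePose(np.array([20., 20., 2.]), np.array([0., 0., 1.]),
                    np.array([1., 0., 0.]))
res = planning.plan_implant(tumor, pose)
m = res.metrics
print(f"status={res.status}  seeds={res.plan.n_seeds}  "
      f"S_K={res.plan.seed_model.air_kerma_strength:.3f} U")
print(f"V100={m.v100:.3f}  V150={m.v150:.3f}  V200={m.v200:.3f}  "
      f"D90={m.d90:.1f} Gy  CI={m.ci:.3f}")

ph, plan, target = qa.default_qa_case(rng_seed=1)
implanted = phantom.implant_seeds(ph, plan, placement_noise_sd=0.43, rng_seed=1)
r = qa.run_implant_qa(implanted, plan, target)
mdev, sdev = r.mean_deviation
print(f"matched {len(r.deviations_mm)}/{r.n_planned} seeds, "
      f"mean deviation {mdev:.2f} +/- {sdev:.2f} mm")
```

Output:

```
status=met  seeds=7  S_K=0.195 U
V100=0.907  V150=0.379  V200=0.122  D90=100.0 Gy  CI=0.570
matched 6/6 seeds, mean deviation 0.39 +/- 0.16 mm
```

The planner met all three prescription constraints on the small target
with seven peripheral seeds of 0.195 U each; QA detected all six implanted
seeds and measured their displacement from the plan (one six-seed draw —
the long-run mean at this noise level is σ√(8/π) ≈ 0.69 mm).

A CLI mirrors these flows: `brachyplan phantom | plan | dose | position |
qa | tables` (see `brachyplan --help`).

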