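# Methods

This note documents the models, parameter defaults, and numerical choices
behind `brachyplan`, and what its synthetic experiments do and do not show
about real implants.

## Frames, units, conventions

Right-handed frame in millimetres, axes aligned to the volume's storage
axes, origin at the centre of voxel (0,0,0), 0-based indices. Angles are
reported in degrees. Internal dose rates are cGy/h (TG-43 convention);
accumulated doses are Gy.

The coplanar template is a rows × cols grid of guide holes at fixed pitch
(default 11 × 11, 5 mm — a standard template geometry). Needles are
assumed rigid and perpendicular to the template plane, so the template's
slant angle equals the acute angle between the first-needle direction and
the image vertical axis; this angle-between-directions definition is used
throughout (it is insensitive to vector sign and scale). Template poses
store an origin (the centre hole), a unit plane normal, and an in-plane x
axis; inputs off-orthonormal by < 1e-6 are re-orthonormalized by
projection, worse inputs rejected. The initial→target motion is the
unique rigid transform mapping one pose frame onto the other; round-trip
residuals are required (and tested) to stay below 1e-9 (mm for origins,
unit-vector mismatch for axes — an arccos-based angle residual cannot be
meaningfully tested at 1e-9° because of floating-point rounding in the
inverse cosine).

## Dose engine

The 1-D (point-source) TG-43 formalism is used:
Ḋ(r) = S_K Λ (r₀/r)² g(r) φ_an(r). The seed is 3.0 × 0.5 mm and planning
resolution is 1 mm, so at planning distances the point approximation is
the standard choice; the 2-D line-source anisotropy F(r,θ), tissue
heterogeneity, and interseed attenuation are out of scope.

* **Bundled seed dataset.** Λ = 0.965 cGy·h⁻¹·U⁻¹, T½ = 59.4 d, a
  near-exponential g(r) on knots 0.5–10 cm and a slowly varying φ_an(r) —
  representative of published consensus-style data for a low-energy ¹²⁵I
  seed. The dataset is a reproducible default, not a claim about any
  specific commercial model; `SeedSource.from_json` overrides everything.
* **Interpolation.** g and φ_an are interpolated log-linearly in r
  (g(r) is near-exponential in water), clamped below the first knot, and
  extrapolated log-linearly above the last (floored at zero).
* **Singularity clamp.** r is clamped to 0.05 cm (configurable) before
  evaluation; voxels inside the capsule otherwise diverge as 1/r².
* **Decay.** Permanent-implant dose uses the closed form
  D = Ḋ₀ τ (1 − e^(−t/τ)), τ = T½/ln 2 = 2056.7 h for ¹²⁵I; the default
  horizon is infinite.
* **Strength from activity.** 1 mCi = 3.7 × 10⁷ Bq (exact);
  S_K = 1.270 U/mCi by default (configurable) — so the 0.7 mCi default
  activity maps to 0.889 U.

Grid dose is the superposition of per-seed doses at voxel-centre to
seed-centre distances; seeds outside the grid still contribute. No
printed dose-engine reference values exist for this study, so the engine
is verified by properties: exact inverse-square behaviour under unit
tables, exact superposition, monotone dose fall-off on the bundled
tables, and closed-form decay checks.

## DVH and plan metrics

The cumulative DVH bins masked voxel doses at 0.1 Gy by default
(fraction receiving ≥ bin dose; first bin 0 Gy → fraction 1). D_x is the
largest dose received by at least x % of the structure, read off the
curve with linear interpolation between bins — accurate to one bin, and
D100 is taken directly as the minimum structure dose. V_d interpolates
the curve at d (exact at bin edges, so V100/V150/V200 with a prescription
on a bin edge equal direct voxel counting). CI is computed by voxel
counting on the shared lattice: V_T the target volume, V_ref the volume
at or above prescription anywhere on the grid, V_T,ref their overlap.
HI = (D₂ − D₉₈)/D_ref × 100.

Group statistics use the sample (n−1) standard deviation; rounding to
printed precision happens only in report/comparison layers. The default
between-group test is the unpaired two-tailed Student t with pooled
variance (Welch and paired variants by flag): applied to the packaged
per-case conformity indices it reproduces the reference p = 0.380. The
packaged homogeneity-index columns do **not** reproduce their reported
p-value under Student, Welch, or paired variants (all give ≈ 0.06–0.08 on
the printed per-case values, against a reported 0.230), so only the CI
p-value is part of the verified surface; the others are computed and
reported as informational.

## Planning

The three-metric prescription (V100 ≥ 90 %, V150 ≤ 50 %, V200 ≤ 20 %;
prescription dose default 100 Gy — an explicit, neutral low-dose-rate
value) drives a deterministic greedy loop:

1. Candidate positions are the template-hole axes sampled at the seed
   pitch (default 5 mm) inside the target.
2. Each step adds the candidate that most increases V100, skipping any
   whose addition would break a hot-spot cap; ties resolve to the lowest
   row-major hole index, then the shallowest depth.
3. The loop stops when constraints are met, the seed budget is exhausted,
   or no candidate improves coverage; coverage is non-decreasing by
   construction.

Greedy placement is the simplest deterministic, fully auditable method
that can satisfy the stated metrics; it makes no claim of optimality.

**Source-strength selection.** With inverse-square point sources the
feasible strength window is set by target size: a strong seed's own 200 %
isodose can exceed the V200 cap outright in a small target, while a weak
seed never reaches prescription. `plan_implant` therefore scans a ladder
of air-kerma strengths (0.05–1.33 U), runs the greedy loop at each, and
additionally tries a continuous rescale of any non-feasible layout (dose
scales linearly in S_K, so feasibility reduces to a one-dimensional scan
over coverage levels of the per-unit-strength dose field). Choosing seed
strength per target is standard planning practice. On the 1-cm spherical
test target this yields a feasible peripheral arrangement (7 seeds of
0.195 U: V100 90.7 %, V150 37.9 %, V200 12.2 %). On the 6.54 cm³
ellipsoid at 100 Gy with a 5-mm template the hot-spot caps genuinely bind
near V100 ≈ 0.89: greedy returns its best cap-respecting plan with an
explicit non-met status rather than overriding a cap.

First-needle selection scores candidates by min–max-normalized widest rib
gap (+), shortest puncture path (−), and largest tumor cross-section (+),
with equal default weights (the criteria are stated qualitatively only);
constant measures normalize to zero and ties resolve to list order.

## Synthetic phantom

The generator emulates the imaging side of a template implant at 1 mm
isotropic voxels: a soft-tissue body block, an ellipsoidal tumor
(default semi-axes 12.5 × 10 × 12.5 mm ≈ 6.54 cm³, the maximum target
size the study conditions call for), optional rib-like bone slabs with a
needle gap, spherical fiducial markers (default radius 2 mm), needles,
and 3.0 × 0.5 mm seeds. Intensities are abstract units — background 0,
soft tissue 100, tumor 160, bone 700, metal 3000 — not calibrated HU.
Gaussian intensity noise (default sd 15 in the reference case) is added
reproducibly from the spec's rng seed; the whole pipeline is
bit-reproducible for fixed seeds.

**Partial volume + PSF.** Metal objects are rendered by evaluating the
object indicator on a 5× sub-voxel grid, convolving it there with an
isotropic Gaussian point-spread function (default σ 0.6 mm, a typical CT
reconstruction blur), and block-averaging to voxels; the result is added
on top of the underlying tissue, peak-normalized to the metal level.
Blurring **before** voxel integration is essential, not cosmetic: it is
what preserves a thin object's sub-voxel centre in the voxel intensities
(convolution preserves the first moment). Without it a 0.5-mm-diameter
seed quantizes laterally to voxel centres and centroid errors reach
~0.4 mm; with it, intensity-weighted centroids recover seed centres to
~0.07 mm (≤ 0.36 mm at noise up to 10 % of the metal contrast).

**Detection.** Voxels at or above the threshold (default midway between
bone and metal) are labeled with 26-connectivity. Per component, the
centroid is weighted by intensity excess over a tissue baseline across
the component dilated by one voxel (wider supports admit too much noise).
Classification is by size: components with peak-normalized mass
≤ 18 voxel-equivalents are seeds (mass is geometry-stable where raw voxel
counts are not — a corner-centred seed spreads over ~16 near-equal
voxels); larger components are needles if their weighted principal-axis
elongation is ≥ 3, else markers (keep marker radii ≥ ~1.8 mm to stay
clearly above the seed band). A needle's tip is estimated from the rod
model: axial variance = L²/12, tip = centroid + (L/2)·axis, axis oriented
along +z (the insertion direction). Planned↔detected matching is
greedy-by-distance mutual pairing under a 5 mm cap.

**Placement noise.** Seed placement error is modelled as an isotropic
per-axis Gaussian offset; its 3-D magnitude then follows a χ(3)
distribution with mean σ√(8/π) and sd σ√(3 − 8/π), which is the analytic
yardstick the QA calibration tests use. Real error sources — needle
deflection, organ motion and deformation, posture change — are explicitly
not modelled, so passing tests demonstrate the correctness of the
planning/QA computations, not clinical positioning accuracy.

## QA workflows

* `run_positioning_workflow` perturbs the planned template pose by a
  given execution error (rotation about the template origin + offset),
  renders the achieved first needle, re-detects its tip, and reports the
  vector-sum error against the planned tip and the achieved slant angle.
* `run_error_validation` is a Monte-Carlo of the repeated positioning
  experiment (default n = 20 per arm, tilt range 0–19°): per-axis folded
  error magnitudes, the vector-sum total, angle error, and a two-arm
  comparison with t-tests. Note the vector-sum mean is σ√(8/π), not the
  root-sum-of-squares of the per-axis folded means; the simulator reports
  both per-axis and total rows so the distinction is visible.
* `run_implant_qa` detects implanted seeds, matches them to the plan,
  reports per-seed deviations (planned seeds without a detected partner
  within 5 mm are flagged and excluded from the average rather than
  crashing the pipeline), and recomputes the dose grid at the detected
  positions for the pre/post metric comparison.
* `published.reproduce_published_tables` recomputes every aggregate cell
  of the packaged reference tables from their per-cell values (means,
  sds, the CI t-test, the vector-sum consistency of the traditional
  method's error row, the activity conversion) and compares at printed
  precision (within half of the last printed digit).

The reference QA case (`default_qa_case`) fixes four needles and six
0.7 mCi seeds in the ellipsoidal target. Six seeds cover only about half
of this maximum-size target at 100 Gy — the case exists to exercise the
deviation/QA pipeline, whose subject is seed positioning, and the
per-case target sizes and prescription of the original experiments are
not available to reproduce their coverage numbers.

## Problem sizes

Default test/acceptance workloads are sized for a single CPU: 64³ voxel
phantoms (32³–48³ in unit tests), 100-phantom detection sweeps, 50-run
implant-QA calibrations, 1000-pose transform round-trips, and
500–2000-draw Monte-Carlo checks; stochastic assertions use fixed seeds
and 3-standard-error bands.

## Known limitations

* 1-D point-source dosimetry only; no heterogeneity, interseed
  attenuation, or line-source anisotropy.
* Greedy placement is order-dependent and can stall at a cap even when a
  globally feasible arrangement exists; the strength ladder and rescale
  mitigate but do not eliminate this.
* The phantom's CT model (additive Gaussian PSF + white noise) omits beam
  hardening, metal streaks, and anisotropic slice profiles; detection
  robustness numbers do not transfer to artifact-heavy clinical scans.
* Robot kinematics, electromagnetic tracking, and DICOM ingestion are out
  of scope.
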