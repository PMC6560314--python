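"""End-to-end QA workflows on synthetic phantoms.

Three workflows mirror the stages of a template-positioning study:

* ``run_positioning_workflow`` -- plan-driven positioning of the template
  with an optional execution perturbation, re-detection of the achieved
  first-needle tip from the rendered volume, and the Euclidean
  (vector-sum) positioning error plus slant-angle report.
* ``run_error_validation`` -- a Monte-Carlo simulator of the repeated
  positioning-error experiment: per-axis Gaussian noise, folded per-axis
  error magnitudes, total (vector-sum) error, angle error, and a
  two-method comparison table with t-tests.
* ``run_implant_qa`` -- post-implant dosimetry QA: detect the implanted
  seeds, match them to the plan, report per-seed deviations and the pre-
  vs post-implant plan metrics (DVH, CI, HI).

``default_qa_case`` builds the package's reference QA fixture: an
ellipsoidal ~6.5 cm^3 target and a four-needle, six-seed plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dosimetry import (ComparisonReport, PlanMetrics, StructureMask,
                        compare_plans, mean_sd, plan_metrics, two_sample_ttest)
from .geometry import (NeedlePath, RigidTransform, TemplateModel, TemplatePose,
                       euclidean_error, slant_angle)
from .phantom import (Phantom, PhantomSpec, detect_objects, generate_phantom,
                      implant_needles, implant_seeds, match_objects)
from .planning import ImplantPlan, PrescriptionConstraints
from .tg43 import SeedSource, default_seed, dose_grid_from_seeds

__all__ = [
    "default_qa_case",
    "PositioningRecord",
    "run_positioning_workflow",
    "ErrorValidationConfig",
    "ErrorValidationReport",
    "run_error_validation",
    "ImplantQAResult",
    "run_implant_qa",
    "deviation_table",
]


def default_qa_case(rng_seed: int = 0, noise_sd: float = 15.0,
                    activity_mci: float = 0.7,
                    prescription: PrescriptionConstraints | None = None
                    ) -> tuple[Phantom, ImplantPlan, StructureMask]:
    """Reference QA fixture: 64 mm^3 phantom, ellipsoidal target, and a
    four-needle / six-seed plan entering along +z through the template."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        tumor_center=(32.0, 32.0, 36.0),
        tumor_radii=(12.5, 10.0, 12.5),
        marker_positions=((14.0, 32.0, 30.0),),
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )
    phantom = generate_phantom(spec)
    template = TemplateModel()
    pose = TemplatePose(np.array([32.0, 32.0, 4.0]),
                        np.array([0.0, 0.0, 1.0]),
                        np.array([1.0, 0.0, 0.0]))
    seeds = np.array([
        [32.0, 32.0, 28.0],
        [32.0, 32.0, 36.0],
        [37.0, 32.0, 32.0],
        [32.0, 37.0, 32.0],
        [37.0, 37.0, 28.0],
        [37.0, 37.0, 36.0],
    ])
    hole_depth = {(5, 5): 32.0, (5, 6): 28.0, (6, 5): 28.0, (6, 6): 32.0}
    needles = tuple(
        NeedlePath(pose.hole_position(template, r, c), pose.normal, depth,
                   entry_hole=(r, c))
        for (r, c), depth in sorted(hole_depth.items())
    )
    plan = ImplantPlan(pose, template, needles, seeds,
                       default_seed(activity_mci),
                       prescription or PrescriptionConstraints())
    return phantom, plan, phantom.tumor_mask()


# ---------------------------------------------------------------------------
# positioning workflow

@dataclass
class PositioningRecord:
    success: bool
    planned_tip: np.ndarray
    achieved_tip: np.ndarray | None
    error_mm: float | None
    planned_slant_deg: float
    achieved_slant_deg: float | None
    angle_error_deg: float | None


def _perturb_pose(pose: TemplatePose, offset_mm, tilt_axis, tilt_deg
                  ) -> TemplatePose:
    """Rotate the pose about its own origin, then translate."""
    r = Rotation.from_rotvec(np.deg2rad(tilt_deg)
                             * np.asarray(tilt_axis, float)
                             / max(np.linalg.norm(tilt_axis), 1e-12)).as_matrix()
    t = RigidTransform(r, pose.origin - r @ pose.origin
                       + np.asarray(offset_mm, float))
    from .geometry import apply_transform
    return apply_transform(t, pose)


def run_positioning_workflow(phantom: Phantom, plan: ImplantPlan,
                             offset_mm=(0.0, 0.0, 0.0),
                             tilt_deg: float = 0.0,
                             tilt_axis=(1.0, 0.0, 0.0),
                             intensity_threshold: float = 1850.0
                             ) -> PositioningRecord:
    """Simulate the plan-driven positioning of the first (locating) needle.

    The planned template pose is perturbed by the given execution error
    (rotation about the template origin, then translation), the achieved
    first needle is rendered into the phantom, and its tip is re-detected
    from the volume and compared with the planned tip (the target point)
    via the vector-sum error; the achieved slant angle is taken from the
    detected needle's principal axis.
    """
    first = plan.needles[0]
    planned_tip = first.tip
    planned_slant = slant_angle(first.direction)

    achieved_pose = _perturb_pose(plan.template_pose, offset_mm, tilt_axis,
                                  tilt_deg)
    hole = first.entry_hole if first.entry_hole is not None \
        else plan.template.center_hole
    entry = achieved_pose.hole_position(plan.template, *hole)
    achieved = NeedlePath(entry, achieved_pose.normal, first.depth,
                          entry_hole=hole)

    rendered = implant_needles(phantom, [achieved])
    det = detect_objects(rendered.volume, spacing=phantom.spec.spacing,
                         intensity_threshold=intensity_threshold,
                         baseline=phantom.spec.intensities.soft_tissue)
    needles = det.of_kind("needle_tip")
    if not needles:
        return PositioningRecord(False, planned_tip, None, None,
                                 planned_slant, None, None)
    best = min(needles, key=lambda o: np.linalg.norm(o.tip - planned_tip))
    achieved_slant = slant_angle(best.principal_axis)
    return PositioningRecord(
        success=True,
        planned_tip=planned_tip,
        achieved_tip=best.tip,
        error_mm=euclidean_error(planned_tip, best.tip),
        planned_slant_deg=planned_slant,
        achieved_slant_deg=achieved_slant,
        angle_error_deg=abs(achieved_slant - planned_slant),
    )


# ---------------------------------------------------------------------------
# error-validation simulator

@dataclass(frozen=True)
class ErrorValidationConfig:
    """One simulated method arm of the repeated positioning experiment."""

    label: str = "method"
    n_repeats: int = 20
    axis_noise_sd_mm: tuple = (0.5, 0.5, 0.5)
    angle_noise_sd_deg: float = 0.3
    angle_range_deg: tuple = (0.0, 19.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if any(s < 0 for s in self.axis_noise_sd_mm) or self.angle_noise_sd_deg < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass
class MethodSamples:
    label: str
    axis_abs_errors: np.ndarray   # (n, 3) per-axis |error| mm
    total_errors: np.ndarray      # (n,) vector-sum error mm
    angle_errors: np.ndarray      # (n,) degrees
    slant_angles: np.ndarray      # (n,) degrees, the tested tilt range


def _simulate(config: ErrorValidationConfig) -> MethodSamples:
    rng = np.random.default_rng(config.rng_seed)
    e = rng.normal(0.0, config.axis_noise_sd_mm, size=(config.n_repeats, 3))
    ang = np.abs(rng.normal(0.0, config.angle_noise_sd_deg, config.n_repeats))
    slants = rng.uniform(*config.angle_range_deg, config.n_repeats)
    return MethodSamples(config.label, np.abs(e),
                         np.linalg.norm(e, axis=1), ang, slants)


@dataclass
class ErrorValidationReport:
    methods: list
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_ROWS = ("x_error_mm", "y_error_mm", "z_error_mm", "total_error_mm",
         "angle_error_deg")


def _method_column(s: MethodSamples) -> dict:
    out = {}
    for k, row in enumerate(_ROWS[:3]):
        m, sd = mean_sd(s.axis_abs_errors[:, k])
        out[row] = (m, sd)
    out["total_error_mm"] = mean_sd(s.total_errors)
    out["angle_error_deg"] = mean_sd(s.angle_errors)
    return out


def run_error_validation(config: ErrorValidationConfig,
                         config_b: ErrorValidationConfig | None = None
                         ) -> ErrorValidationReport:
    """Simulate one or two method arms and lay the summary out as a
    per-parameter mean +/- sd table (plus t-test p-values for two arms)."""
    arms = [_simulate(config)]
    if config_b is not None:
        arms.append(_simulate(config_b))
    cols = [_method_column(s) for s in arms]
    records = []
    records.append({
        "parameter": "angle_range_deg",
        **{s.label + "_mean": cfg.angle_range_deg[0] for s, cfg in
           zip(arms, [config, config_b][:len(arms)])},
        **{s.label + "_max": cfg.angle_range_deg[1] for s, cfg in
           zip(arms, [config, config_b][:len(arms)])},
    })
    for row in _ROWS:
        rec = {"parameter": row}
        for s, col in zip(arms, cols):
            rec[s.label + "_mean"], rec[s.label + "_sd"] = col[row]
        if len(arms) == 2:
            a = arms[0].axis_abs_errors[:, _ROWS.index(row)] \
                if row in _ROWS[:3] else \
                (arms[0].total_errors if row == "total_error_mm"
                 else arms[0].angle_errors)
            b = arms[1].axis_abs_errors[:, _ROWS.index(row)] \
                if row in _ROWS[:3] else \
                (arms[1].total_errors if row == "total_error_mm"
                 else arms[1].angle_errors)
            rec["p"] = two_sample_ttest(a, b).p
        records.append(rec)
    return ErrorValidationReport(arms, pd.DataFrame(records))


# ---------------------------------------------------------------------------
# implant QA

@dataclass
class ImplantQAResult:
    deviations_mm: np.ndarray       # matched per-seed vector-sum deviations
    n_planned: int
    n_detected: int
    n_excluded: int                 # planned seeds without a detected partner
    pre_metrics: PlanMetrics
    post_metrics: PlanMetrics

    @property
    def mean_deviation(self) -> tuple:
        return mean_sd(self.deviations_mm)


def run_implant_qa(implanted: Phantom, plan: ImplantPlan,
                   tumor: StructureMask | None = None,
                   intensity_threshold: float = 1850.0,
                   max_match_distance: float = 5.0,
                   bin_width: float = 0.1,
                   horizon_days: float = math.inf) -> ImplantQAResult:
    """Detect implanted seeds, match to the plan, and compare dosimetry.

    Planned seeds with no detected partner within the distance cap are
    excluded from the deviation average and counted; the post-implant dose
    grid is recomputed at the detected seed centres with the planned seed
    model.
    """
    tumor = tumor or implanted.tumor_mask()
    det = detect_objects(implanted.volume, spacing=implanted.spec.spacing,
                         intensity_threshold=intensity_threshold,
                         baseline=implanted.spec.intensities.tumor)
    detected = det.centers("seed")
    match = match_objects(plan.seed_positions, detected,
                          max_distance=max_match_distance)
    deviations = match.distances

    grid = tumor.spec
    presc = plan.prescription.prescription_dose
    pre_dose = dose_grid_from_seeds(plan.seed_pairs(), grid,
                                    horizon_days=horizon_days)
    pre = plan_metrics(pre_dose, tumor, presc, bin_width=bin_width)
    if len(detected):
        post_dose = dose_grid_from_seeds(
            [(p, plan.seed_model) for p in detected], grid,
            horizon_days=horizon_days)
        post = plan_metrics(post_dose, tumor, presc, bin_width=bin_width)
    else:
        post = None
    return ImplantQAResult(
        deviations_mm=deviations,
        n_planned=plan.n_seeds,
        n_detected=len(detected),
        n_excluded=len(match.unmatched_planned),
        pre_metrics=pre,
        post_metrics=post,
    )


def deviation_table(results: list[ImplantQAResult]) -> pd.DataFrame:
    """Per-case seed-deviation table: one row per case with per-seed
    deviations, the case average +/- sd, and the coverage (V100 %); a final
    row holds the grand mean +/- sd of the case averages."""
    if not results:
        raise ValueError("no QA results")
    rows = []
    case_means = []
    for i, r in enumerate(results, start=1):
        m, sd = mean_sd(r.deviations_mm) if len(r.deviations_mm) else (np.nan, np.nan)
        case_means.append(m)
        rows.append({
            "case": str(i),
            **{f"d{j + 1}": d for j, d in enumerate(r.deviations_mm)},
            "ave_mm": m, "ave_sd_mm": sd,
            "excluded": r.n_excluded,
            "v100_pct": r.post_metrics.v100 * 100.0 if r.post_metrics else np.nan,
        })
    gm, gsd = mean_sd([m for m in case_means if np.isfinite(m)])
    rows.append({"case": "Mean", "ave_mm": gm, "ave_sd_mm": gsd})
    return pd.DataFrame(rows)
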