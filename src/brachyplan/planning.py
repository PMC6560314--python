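"""Implant planning: first-needle selection and constraint-driven seed
placement on a coplanar template.

The planning objective is the standard three-metric prescription used for
thoracoabdominal seed implants: at least 90% of the target volume must
receive 100% of the prescription dose (V100 >= 0.90) while the hot-spot
fractions stay bounded (V150 <= 0.50, V200 <= 0.20).

Seed placement is a deterministic greedy loop over the candidate lattice
formed by the template's hole axes sampled at the seed pitch inside the
target: at each step the candidate that most increases V100 is added,
skipping any candidate that would break a hot-spot cap, until the
constraints are met, the seed budget is exhausted, or no candidate
improves coverage.  ``plan_implant`` wraps the greedy loop with per-seed
source-strength selection (a strength ladder plus a continuous rescale),
because with inverse-square point sources the feasible strength window is
set by the target size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import NeedlePath, TemplateModel, TemplatePose
from .tg43 import (DoseGrid, GridSpec, SeedSource, cumulative_dose,
                   default_seed, dose_grid_from_seeds, dose_rate_at)
from .dosimetry import PlanMetrics, StructureMask, plan_metrics

__all__ = [
    "PrescriptionConstraints",
    "CandidateNeedle",
    "ImplantPlan",
    "ConstraintCheck",
    "PlanResult",
    "select_first_needle",
    "evaluate_plan",
    "check_constraints",
    "greedy_seed_placement",
    "plan_implant",
]


@dataclass(frozen=True)
class PrescriptionConstraints:
    """Prescription dose plus the three coverage/hot-spot constraints."""

    prescription_dose: float = 100.0  # Gy, neutral low-dose-rate default
    min_v100: float = 0.90
    max_v150: float = 0.50
    max_v200: float = 0.20

    def __post_init__(self):
        if not self.prescription_dose > 0:
            raise ValueError("prescription dose must be positive")
        for f in (self.min_v100, self.max_v150, self.max_v200):
            if not 0 < f <= 1:
                raise ValueError("constraint fractions must be in (0, 1]")
        if self.max_v200 > self.max_v150:
            raise ValueError("max_v200 cannot exceed max_v150")


@dataclass(frozen=True)
class CandidateNeedle:
    """A candidate first (locating) needle with its selection measures."""

    path: NeedlePath
    rib_gap_width: float          # mm, widest rib gap along this approach
    puncture_length: float        # mm, skin-to-target path length
    tumor_cross_section_area: float  # mm^2 at the needle's template plane

    def __post_init__(self):
        for v in (self.rib_gap_width, self.puncture_length,
                  self.tumor_cross_section_area):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError("candidate measures must be finite and >= 0")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def select_first_needle(candidates: Sequence[CandidateNeedle],
                        weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
                        ) -> CandidateNeedle:
    """Pick the locating needle: widest rib gap, shortest puncture path,
    largest tumor cross-section, combined by min-max-normalized weighted
    score; deterministic tie-break by list order."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate needle is required")
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("weights must be 3 non-negative numbers")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    w = w / w.sum()
    gap = _minmax(np.array([c.rib_gap_width for c in candidates]))
    length = _minmax(np.array([c.puncture_length for c in candidates]))
    area = _minmax(np.array([c.tumor_cross_section_area for c in candidates]))
    score = w[0] * gap - w[1] * length + w[2] * area
    return candidates[int(np.argmax(score))]  # argmax takes the first maximum


@dataclass(frozen=True)
class ImplantPlan:
    """Needle paths through template holes plus planned seed centres."""

    template_pose: TemplatePose
    template: TemplateModel
    needles: tuple
    seed_positions: np.ndarray          # (n, 3) mm
    seed_model: SeedSource
    prescription: PrescriptionConstraints

    def __post_init__(self):
        sp = np.atleast_2d(np.asarray(self.seed_positions, dtype=float))
        if sp.shape[0] < 1 or sp.shape[1] != 3 or not np.all(np.isfinite(sp)):
            raise ValueError("plan needs >= 1 finite seed position")
        needles = tuple(self.needles)
        if not needles:
            raise ValueError("plan needs >= 1 needle")
        # every seed must lie on some needle axis (within half the hole pitch)
        tol = self.template.hole_spacing / 2.0
        for s in sp:
            d = min(_axis_distance(s, nd) for nd in needles)
            if d > tol:
                raise ValueError(f"seed {s} is {d:.2f} mm off every needle axis")
        object.__setattr__(self, "needles", needles)
        object.__setattr__(self, "seed_positions", sp)

    @property
    def n_seeds(self) -> int:
        return self.seed_positions.shape[0]

    def seed_pairs(self):
        return [(p, self.seed_model) for p in self.seed_positions]

    def to_json_dict(self) -> dict:
        return {
            "template_pose": self.template_pose.to_dict(),
            "template": {"rows": self.template.rows, "cols": self.template.cols,
                         "hole_spacing": self.template.hole_spacing,
                         "center_hole": list(self.template.center_hole)},
            "needles": [n.to_dict() for n in self.needles],
            "seed_positions_mm": [[float(x) for x in p] for p in self.seed_positions],
            "seed_model": self.seed_model.name,
            "seed_air_kerma_strength_U": float(self.seed_model.air_kerma_strength),
            "prescription_Gy": self.prescription.prescription_dose,
            "constraints": {"min_v100": self.prescription.min_v100,
                            "max_v150": self.prescription.max_v150,
                            "max_v200": self.prescription.max_v200},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_json_dict(), f, indent=1, sort_keys=True)


def _axis_distance(point: np.ndarray, needle: NeedlePath) -> float:
    v = point - needle.entry
    along = np.dot(v, needle.direction)
    return float(np.linalg.norm(v - along * needle.direction))


@dataclass(frozen=True)
class ConstraintCheck:
    v100_ok: bool
    v150_ok: bool
    v200_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.v100_ok and self.v150_ok and self.v200_ok


def check_constraints(metrics: PlanMetrics,
                      constraints: PrescriptionConstraints) -> ConstraintCheck:
    """Inclusive per-constraint pass/fail: V100 >= min, V150/V200 <= max."""
    return ConstraintCheck(
        v100_ok=bool(metrics.v100 >= constraints.min_v100),
        v150_ok=bool(metrics.v150 <= constraints.max_v150),
        v200_ok=bool(metrics.v200 <= constraints.max_v200),
    )


def evaluate_plan(plan: ImplantPlan, tumor: StructureMask,
                  grid: GridSpec | None = None,
                  bin_width: float = 0.1,
                  horizon_days: float = math.inf) -> PlanMetrics:
    """Dose grid -> DVH -> PlanMetrics for a plan; pure function of inputs."""
    if tumor.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    grid = grid or tumor.spec
    dose = dose_grid_from_seeds(plan.seed_pairs(), grid, horizon_days=horizon_days)
    return plan_metrics(dose, tumor, plan.prescription.prescription_dose,
                        bin_width=bin_width)


# ---------------------------------------------------------------------------
# greedy placement

@dataclass
class PlanResult:
    """Outcome of a placement run. ``status`` is one of
    'met' (all constraints satisfied), 'max_seeds', 'stalled'
    (no candidate improves V100 without breaking a cap), or 'infeasible'
    (no seed could be placed at all; ``plan`` is then None)."""

    plan: ImplantPlan | None
    status: str
    v100_trace: list
    metrics: PlanMetrics | None = None

    @property
    def feasible(self) -> bool:
        return self.status == "met"


def _candidate_lattice(tumor: StructureMask, pose: TemplatePose,
                       template: TemplateModel, seed_pitch: float):
    """Candidate seed centres: hole axes x depth steps of ``seed_pitch``
    that fall inside the tumor mask.  Ordered by (hole row-major index,
    depth) for the deterministic tie-break."""
    spec = tumor.spec
    idx = np.argwhere(tumor.mask)
    if idx.size == 0:
        raise ValueError("tumor mask is empty")
    origin = np.asarray(spec.origin)
    spacing = np.asarray(spec.spacing)
    pts_mm = idx * spacing + origin
    # depth range: projection of the tumor voxels onto the needle axis
    t_all = (pts_mm - pose.origin) @ pose.normal
    t_lo, t_hi = float(t_all.min()) - seed_pitch, float(t_all.max()) + seed_pitch
    depths = np.arange(max(seed_pitch, t_lo), t_hi + 1e-9, seed_pitch)
    candidates = []  # (hole_index, depth, position)
    for hi_idx, (r, c) in enumerate(template.holes()):
        entry = pose.hole_position(template, r, c)
        for t in depths:
            p = entry + t * pose.normal
            v = np.round((p - origin) / spacing).astype(int)
            if np.any(v < 0) or np.any(v >= np.asarray(spec.shape)):
                continue
            if tumor.mask[tuple(v)]:
                candidates.append((hi_idx, (r, c), float(t), p))
    return candidates


def _candidate_dose_matrix(positions, seed: SeedSource, coords_mm: np.ndarray,
                           horizon_days: float) -> np.ndarray:
    """(n_candidates, n_voxels) accumulated dose of one seed at each
    candidate position, evaluated at the given voxel centres."""
    out = np.empty((len(positions), coords_mm.shape[0]))
    for j, p in enumerate(positions):
        r_cm = np.linalg.norm(coords_mm - p, axis=1) / 10.0
        out[j] = cumulative_dose(dose_rate_at(seed, r_cm), seed.half_life_days,
                                 horizon_days)
    return out


def greedy_seed_placement(tumor: StructureMask, pose: TemplatePose,
                          template: TemplateModel,
                          seed_model: SeedSource | None = None,
                          constraints: PrescriptionConstraints | None = None,
                          seed_pitch: float = 5.0,
                          max_seeds: int = 30,
                          horizon_days: float = math.inf) -> PlanResult:
    """Deterministic greedy V100-maximizing seed placement under hot-spot caps.

    Ties in V100 gain resolve to the lowest hole index (row-major), then the
    shallowest depth.  The returned plan's needles are exactly the holes
    that received seeds, with depth reaching the deepest seed on each.
    """
    seed_model = seed_model or default_seed()
    constraints = constraints or PrescriptionConstraints()
    if tumor.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    if seed_pitch <= 0:
        raise ValueError("seed_pitch must be positive")

    cands = _candidate_lattice(tumor, pose, template, seed_pitch)
    if max_seeds <= 0 or not cands:
        return PlanResult(None, "infeasible", [])

    spec = tumor.spec
    coords = (np.argwhere(tumor.mask) * np.asarray(spec.spacing)
              + np.asarray(spec.origin))
    n_vox = coords.shape[0]
    presc = constraints.prescription_dose
    dose_mat = _candidate_dose_matrix([c[3] for c in cands], seed_model,
                                      coords, horizon_days)

    used: list[int] = []
    current = np.zeros(n_vox)
    n100 = 0
    need100 = constraints.min_v100 * n_vox
    cap150 = constraints.max_v150 * n_vox
    cap200 = constraints.max_v200 * n_vox
    trace: list[float] = []
    status = "stalled"
    while len(used) < max_seeds:
        best_j, best_gain = -1, 0
        for j in range(len(cands)):
            if j in used:
                continue
            trial = current + dose_mat[j]
            if (trial >= 1.5 * presc).sum() > cap150:
                continue
            if (trial >= 2.0 * presc).sum() > cap200:
                continue
            gain = int((trial >= presc).sum()) - n100
            if gain > best_gain:  # strict: first max wins ties via candidate order
                best_j, best_gain = j, gain
        if best_j < 0:
            status = "stalled"
            break
        used.append(best_j)
        current += dose_mat[best_j]
        n100 = int((current >= presc).sum())
        trace.append(n100 / n_vox)
        if n100 >= need100:
            status = "met"
            break
    else:
        status = "max_seeds" if n100 < need100 else status

    if not used:
        return PlanResult(None, "infeasible", trace)

    plan = _assemble_plan(cands, used, pose, template, seed_model, constraints)
    return PlanResult(plan, status, trace)


def _assemble_plan(cands, used, pose, template, seed_model, constraints):
    by_hole: dict[tuple[int, int], list[float]] = {}
    positions = []
    for j in sorted(used):
        _, hole, t, p = cands[j]
        by_hole.setdefault(hole, []).append(t)
        positions.append(p)
    needles = []
    for hole in sorted(by_hole):
        r, c = hole
        entry = pose.hole_position(template, r, c)
        needles.append(NeedlePath(entry, pose.normal, max(by_hole[hole]),
                                  entry_hole=hole))
    return ImplantPlan(pose, template, tuple(needles), np.array(positions),
                       seed_model, constraints)


# strength ladder in U; ~0.04-1.3 mCi equivalent, spanning small to large targets
_DEFAULT_STRENGTHS_U = (0.05, 0.08, 0.12, 0.18, 0.27, 0.40, 0.60, 0.889, 1.33)


def _rescaled_strength(result: PlanResult, tumor: StructureMask,
                       constraints: PrescriptionConstraints,
                       horizon_days: float) -> float | None:
    """Continuous source-strength refinement for a fixed seed layout.

    Dose scales linearly in S_K, so feasibility reduces to finding a dose
    level a with frac(F >= a) >= min_v100, frac(F >= 1.5a) <= max_v150 and
    frac(F >= 2a) <= max_v200, where F is the per-unit-strength dose field
    on the target.  Scans candidate levels at the coverage quantile and
    below; returns the feasible strength of smallest hot-spot load, or None.
    """
    if result.plan is None:
        return None
    spec = tumor.spec
    coords = (np.argwhere(tumor.mask) * np.asarray(spec.spacing)
              + np.asarray(spec.origin))
    seed = result.plan.seed_model
    unit = seed.with_strength(1.0)
    f = np.zeros(coords.shape[0])
    for p in result.plan.seed_positions:
        r_cm = np.linalg.norm(coords - p, axis=1) / 10.0
        f += cumulative_dose(dose_rate_at(unit, r_cm), seed.half_life_days,
                             horizon_days)
    n = f.size
    presc = constraints.prescription_dose
    # a = quantile(F, 1 - min_v100) gives V100 exactly at the bound; sweep
    # toward fuller coverage and accept the first level whose caps hold
    for q in np.linspace(1.0 - constraints.min_v100, 0.0, 25):
        a = float(np.quantile(f, q))
        if a <= 0:
            continue
        if (f >= 1.5 * a).sum() <= constraints.max_v150 * n and \
                (f >= 2.0 * a).sum() <= constraints.max_v200 * n:
            return presc / a  # S_K such that dose level a maps to prescription
    return None


def plan_implant(tumor: StructureMask, pose: TemplatePose,
                 template: TemplateModel | None = None,
                 constraints: PrescriptionConstraints | None = None,
                 base_seed: SeedSource | None = None,
                 strengths_u: Sequence[float] = _DEFAULT_STRENGTHS_U,
                 seed_pitch: float = 5.0, max_seeds: int = 30,
                 horizon_days: float = math.inf) -> PlanResult:
    """Greedy placement with per-seed strength selection.

    Runs the greedy loop at each strength of a ladder; if a run is not
    already feasible, attempts a continuous strength rescale of its layout.
    Returns the first fully feasible plan (lowest workable strength), else
    the best-coverage cap-respecting result found.
    """
    template = template or TemplateModel()
    constraints = constraints or PrescriptionConstraints()
    base_seed = base_seed or default_seed()
    best: PlanResult | None = None
    for s in strengths_u:
        seed = base_seed.with_strength(float(s))
        res = greedy_seed_placement(tumor, pose, template, seed, constraints,
                                    seed_pitch=seed_pitch, max_seeds=max_seeds,
                                    horizon_days=horizon_days)
        if res.plan is not None and res.status != "met":
            s_new = _rescaled_strength(res, tumor, constraints, horizon_days)
            if s_new is not None:
                seed2 = base_seed.with_strength(s_new * 1.0)
                plan2 = replace(res.plan, seed_model=seed2)
                m2 = evaluate_plan(plan2, tumor, horizon_days=horizon_days)
                if check_constraints(m2, constraints).all_ok:
                    return PlanResult(plan2, "met", res.v100_trace, m2)
        if res.plan is not None:
            m = evaluate_plan(res.plan, tumor, horizon_days=horizon_days)
            res.metrics = m
            if check_constraints(m, constraints).all_ok:
                res.status = "met"
                return res
            if best is None or (res.v100_trace and best.v100_trace
                                and res.v100_trace[-1] > best.v100_trace[-1]):
                best = res
    return best if best is not None else PlanResult(None, "infeasible", [])
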