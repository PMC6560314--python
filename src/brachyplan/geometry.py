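"""Pose, angle, and error geometry for template-guided needle implants.

All lengths are millimetres in a right-handed image frame (axes aligned to
the volume storage axes, origin at the first voxel centre); all angles are
reported in degrees.  The coplanar template is modelled as a rectangular
grid of parallel guide holes; needles pass through holes perpendicular to
the template plane, and the template's tilt ("slant angle") therefore
equals the first needle's angle from the image vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "euclidean_error",
    "angle_between",
    "slant_angle",
    "RigidTransform",
    "TemplateModel",
    "TemplatePose",
    "NeedlePath",
    "template_pose_from_plan",
    "relative_transform",
    "apply_transform",
    "needle_paths_from_template",
]

#: default reference axis for slant angles: the image vertical (z) axis
VERTICAL = np.array([0.0, 0.0, 1.0])

_ORTHO_TOL = 1e-9          # strict orthonormality tolerance
_REORTHO_TOL = 1e-6        # inputs within this are re-orthonormalized


def _as_vec(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite components: {a}")
    return a


def euclidean_error(p, q) -> float:
    """Positioning error e_E = sqrt((xP-xQ)^2 + (yP-yQ)^2 + (zP-zQ)^2) in mm.

    The standard deviation metric between a needle tip (or seed) and its
    planned target point; symmetric and non-negative.
    """
    p = _as_vec(p, "p")
    q = _as_vec(q, "q")
    return float(np.linalg.norm(p - q))


def angle_between(u, v) -> float:
    """Acute angle between two directions, in degrees within [0, 90].

    Orientation-insensitive: arccos(|u.v| / (|u||v|)), invariant to scaling
    and sign flips of either vector.
    """
    u = _as_vec(u, "u")
    v = _as_vec(v, "v")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_between requires nonzero vectors")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def slant_angle(m, reference_axis=VERTICAL) -> float:
    """Template slant angle from the first-needle direction ``m``, degrees.

    Needles run perpendicular to the template plane, so the needle's acute
    angle from the image vertical axis equals the template's tilt from
    horizontal.
    """
    return angle_between(m, reference_axis)


def _unit(v, name: str = "direction") -> np.ndarray:
    v = _as_vec(v, name)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} is degenerate (near-zero norm)")
    return v / n


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation; rotation is orthonormal with det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = _as_vec(self.translation, "translation")
        if r.shape != (3, 3) or not np.all(np.isfinite(r)):
            raise ValueError("rotation must be a finite 3x3 matrix")
        err = np.abs(r @ r.T - np.eye(3)).max()
        if err > _REORTHO_TOL:
            raise ValueError(f"rotation is not orthonormal (deviation {err:.3g})")
        if err > _ORTHO_TOL:
            # project onto SO(3) via SVD
            u, _, vt = np.linalg.svd(r)
            r = u @ vt
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_point(self, p) -> np.ndarray:
        return self.rotation @ _as_vec(p, "point") + self.translation

    def apply_vector(self, v) -> np.ndarray:
        return self.rotation @ _as_vec(v, "vector")

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],  # row-major
            "translation": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], dtype=float).reshape(3, 3),
                   np.asarray(d["translation"], dtype=float))


@dataclass(frozen=True)
class TemplateModel:
    """Coplanar template: a rows x cols grid of guide holes at fixed pitch."""

    rows: int = 11
    cols: int = 11
    hole_spacing: float = 5.0  # mm
    center_hole: tuple[int, int] = (5, 5)

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("template grid must have at least one hole")
        if self.hole_spacing <= 0:
            raise ValueError("hole_spacing must be positive")
        r, c = self.center_hole
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ValueError("center_hole outside the hole grid")

    def hole_offset(self, row: int, col: int) -> tuple[float, float]:
        """In-plane (x, y) offset of a hole from the centre hole, mm."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"hole {(row, col)} outside {self.rows}x{self.cols} grid")
        r0, c0 = self.center_hole
        return ((col - c0) * self.hole_spacing, (row - r0) * self.hole_spacing)

    def holes(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]


@dataclass(frozen=True)
class TemplatePose:
    """Template position/orientation: centre-hole origin + plane frame.

    ``normal`` is the unit plane normal (the common needle direction);
    ``in_plane_x`` is a unit vector in the template plane.  The in-plane y
    axis completes a right-handed frame.  Inputs off-orthonormal by less
    than 1e-6 are re-orthonormalized by projection; worse inputs are
    rejected.
    """

    origin: np.ndarray
    normal: np.ndarray
    in_plane_x: np.ndarray

    def __post_init__(self):
        o = _as_vec(self.origin, "origin")
        n = _as_vec(self.normal, "normal")
        x = _as_vec(self.in_plane_x, "in_plane_x")
        if abs(np.linalg.norm(n) - 1.0) > _REORTHO_TOL or \
           abs(np.linalg.norm(x) - 1.0) > _REORTHO_TOL or \
           abs(float(np.dot(n / np.linalg.norm(n), x / np.linalg.norm(x)))) > _REORTHO_TOL:
            raise ValueError("pose frame is not orthonormal within 1e-6")
        n = n / np.linalg.norm(n)
        x = x - np.dot(x, n) * n  # project off the normal
        x = x / np.linalg.norm(x)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "in_plane_x", x)

    @property
    def in_plane_y(self) -> np.ndarray:
        return np.cross(self.normal, self.in_plane_x)

    @property
    def rotation(self) -> np.ndarray:
        """Frame matrix with columns (in_plane_x, in_plane_y, normal)."""
        return np.column_stack([self.in_plane_x, self.in_plane_y, self.normal])

    def hole_position(self, template: TemplateModel, row: int, col: int) -> np.ndarray:
        dx, dy = template.hole_offset(row, col)
        return self.origin + dx * self.in_plane_x + dy * self.in_plane_y

    def to_dict(self) -> dict:
        return {
            "origin": [float(v) for v in self.origin],
            "normal": [float(v) for v in self.normal],
            "in_plane_x": [float(v) for v in self.in_plane_x],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplatePose":
        return cls(np.asarray(d["origin"], float),
                   np.asarray(d["normal"], float),
                   np.asarray(d["in_plane_x"], float))


@dataclass(frozen=True)
class NeedlePath:
    """A straight (rigid, non-bending) needle through one template hole."""

    entry: np.ndarray            # skin/template-side entry point, mm
    direction: np.ndarray        # unit vector, parallel to the template normal
    depth: float                 # insertion depth from entry to tip, mm
    entry_hole: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "entry", _as_vec(self.entry, "entry"))
        object.__setattr__(self, "direction", _unit(self.direction))
        if not np.isfinite(self.depth) or self.depth <= 0:
            raise ValueError("depth must be positive and finite")

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.depth * self.direction

    def point_at(self, t: float) -> np.ndarray:
        return self.entry + t * self.direction

    def to_dict(self) -> dict:
        return {
            "entry": [float(v) for v in self.entry],
            "direction": [float(v) for v in self.direction],
            "depth": float(self.depth),
            "entry_hole": list(self.entry_hole) if self.entry_hole is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeedlePath":
        hole = d.get("entry_hole")
        return cls(np.asarray(d["entry"], float), np.asarray(d["direction"], float),
                   float(d["depth"]), tuple(hole) if hole is not None else None)


def _perpendicular(n: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to n: Gram-Schmidt against the
    world axis least aligned with n."""
    axes = np.eye(3)
    k = int(np.argmin(np.abs(axes @ n)))
    x = axes[k] - np.dot(axes[k], n) * n
    return x / np.linalg.norm(x)


def template_pose_from_plan(first_needle: NeedlePath, template: TemplateModel,
                            standoff: float) -> TemplatePose:
    """Pose of a template whose centre hole carries the first needle.

    The template plane sits ``standoff`` mm behind the skin entry point,
    measured back along the needle line; its normal is the needle direction.
    """
    if not np.isfinite(standoff) or standoff <= 0:
        raise ValueError("standoff must be positive")
    n = first_needle.direction
    origin = first_needle.entry - standoff * n
    return TemplatePose(origin, n, _perpendicular(n))


def relative_transform(initial: TemplatePose, target: TemplatePose) -> RigidTransform:
    """The unique rigid motion mapping the initial template frame onto the
    target frame (the relative coordinate sent to the positioning robot)."""
    r = target.rotation @ initial.rotation.T
    t = target.origin - r @ initial.origin
    return RigidTransform(r, t)


def apply_transform(t: RigidTransform, pose: TemplatePose) -> TemplatePose:
    return TemplatePose(
        t.apply_point(pose.origin),
        t.apply_vector(pose.normal),
        t.apply_vector(pose.in_plane_x),
    )


def needle_paths_from_template(pose: TemplatePose, template: TemplateModel,
                               holes: Iterable[tuple[int, int]],
                               depth: float) -> list[NeedlePath]:
    """Parallel needle paths through the given holes, all at one depth."""
    if not np.isfinite(depth) or depth <= 0:
        raise ValueError("depth must be positive")
    paths = []
    for (r, c) in holes:
        entry = pose.hole_position(template, r, c)
        paths.append(NeedlePath(entry, pose.normal, depth, entry_hole=(r, c)))
    return paths
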