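"""Synthetic CT-like voxel phantoms and object recovery.

The generator emulates the imaging side of a template-guided implant: a
soft-tissue body containing an ellipsoidal tumor target, optional rib-like
bone slabs with needle gaps, spherical fiducial markers, implant needles,
and cylindrical 3.0 x 0.5 mm seeds, rendered at (by default) 1 mm voxels.

Intensities are abstract units, not calibrated HU: background 0, soft
tissue 100, tumor 160, bone 700, metal 3000.  Metal objects are rendered
with supersampled partial-volume occupancy -- each voxel's intensity excess
over its surroundings is proportional to the fraction of the voxel inside
the object, peak-normalized to the metal level -- which models CT
partial-volume averaging and lets intensity-weighted centroids recover
object centres to a small fraction of a voxel.

Detection is threshold + 26-connected component labeling with voxel-count
band classification (seed / marker / needle), a documented stand-in for a
TPS's automatic seed pickup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dosimetry import StructureMask
from .tg43 import GridSpec

__all__ = [
    "Intensities",
    "RibSlab",
    "PhantomSpec",
    "TruthObject",
    "Phantom",
    "DetectedObject",
    "DetectionResult",
    "generate_phantom",
    "implant_seeds",
    "implant_needles",
    "detect_objects",
    "match_objects",
]


@dataclass(frozen=True)
class Intensities:
    background: float = 0.0
    soft_tissue: float = 100.0
    tumor: float = 160.0
    bone: float = 700.0
    metal: float = 3000.0


@dataclass(frozen=True)
class RibSlab:
    """Bone slab at depth z in [position, position+thickness] spanning the
    body cross-section, with a needle gap of ``gap_width`` (mm) centred on
    ``gap_center_x`` (defaults to the tumor centre x)."""

    position: float
    thickness: float
    gap_width: float
    gap_center_x: float | None = None


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (64, 64, 64)
    spacing: float = 1.0                      # mm, isotropic
    tumor_center: tuple = (32.0, 32.0, 32.0)  # mm
    tumor_radii: tuple = (12.5, 10.0, 12.5)   # mm semi-axes (~6.54 cm^3)
    rib_slabs: tuple = ()
    marker_positions: tuple = ()
    marker_radius: float = 2.0                # mm
    psf_sigma_mm: float = 0.6                 # reconstruction blur (PSF)
    intensities: Intensities = Intensities()
    noise_sd: float = 0.0                     # intensity units
    body_margin: int = 2                      # voxels of air around the body
    rng_seed: int = 0

    def __post_init__(self):
        if any(int(n) < 16 for n in self.shape):
            raise ValueError("phantom dims must each be >= 16 voxels")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        c = np.asarray(self.tumor_center, float)
        r = np.asarray(self.tumor_radii, float)
        ext = np.asarray(self.shape) * self.spacing
        if np.any(r <= 0):
            raise ValueError("tumor radii must be positive")
        if np.any(c - r < 0) or np.any(c + r > ext):
            raise ValueError("tumor extends outside the volume")
        for m in self.marker_positions:
            if np.any(np.asarray(m, float) < 0) or np.any(np.asarray(m, float) > ext):
                raise ValueError(f"marker {m} outside the volume")

    @property
    def grid(self) -> GridSpec:
        return GridSpec((0.0, 0.0, 0.0), (self.spacing,) * 3, tuple(self.shape))


@dataclass(frozen=True)
class TruthObject:
    kind: str                   # 'seed' | 'marker' | 'needle'
    center: np.ndarray          # mm (for needles: the tip)
    direction: np.ndarray | None = None
    size_mm: float | None = None
    clipped: bool = False


@dataclass
class Phantom:
    spec: PhantomSpec
    volume: np.ndarray
    truth: list

    def tumor_mask(self) -> StructureMask:
        return StructureMask(self.spec.grid, _ellipsoid_mask(self.spec))

    def copy(self) -> "Phantom":
        return Phantom(self.spec, self.volume.copy(), list(self.truth))


def _axes_mm(spec: PhantomSpec):
    return tuple(spec.spacing * np.arange(n) for n in spec.shape)


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    ax = _axes_mm(spec)
    c = np.asarray(spec.tumor_center, float)
    r = np.asarray(spec.tumor_radii, float)
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return ((gx - c[0]) ** 2 / r[0] ** 2 + (gy - c[1]) ** 2 / r[1] ** 2
            + (gz - c[2]) ** 2 / r[2] ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render the body/tumor/rib/marker phantom; bit-reproducible per seed."""
    ints = spec.intensities
    vol = np.full(spec.shape, ints.background, dtype=float)
    m = spec.body_margin
    body = np.zeros(spec.shape, dtype=bool)
    body[m:spec.shape[0] - m, m:spec.shape[1] - m, m:spec.shape[2] - m] = True
    vol[body] = ints.soft_tissue
    vol[_ellipsoid_mask(spec)] = ints.tumor

    ax = _axes_mm(spec)
    for rib in spec.rib_slabs:
        gap_cx = rib.gap_center_x if rib.gap_center_x is not None \
            else spec.tumor_center[0]
        zsel = (ax[2] >= rib.position) & (ax[2] <= rib.position + rib.thickness)
        xsel = np.abs(ax[0] - gap_cx) > rib.gap_width / 2.0
        region = np.zeros(spec.shape, dtype=bool)
        region[np.ix_(xsel, np.ones(spec.shape[1], bool), zsel)] = True
        vol[region & body] = ints.bone

    truth: list[TruthObject] = []
    for mk in spec.marker_positions:
        c = np.asarray(mk, float)
        _render_sphere(vol, spec, c, spec.marker_radius, ints.metal)
        truth.append(TruthObject("marker", c, size_mm=spec.marker_radius))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return Phantom(spec, vol, truth)


# ------------------------------------------------------------------
# partial-volume rendering

_SUPERSAMPLE = 5  # subsamples per voxel edge


def _occupancy(spec: PhantomSpec, lo_idx, hi_idx, inside_fn) -> np.ndarray:
    """Per-voxel PSF-blurred occupancy of a shape over voxels [lo, hi).

    The shape's indicator is evaluated on a regular sub-voxel grid,
    convolved there with the isotropic Gaussian reconstruction blur
    (``psf_sigma_mm``), and block-averaged to voxels.  Blurring before the
    voxel integration is what preserves an object's sub-voxel centre in
    the voxel intensities (convolution keeps the first moment); a thin
    object integrated directly to voxels would quantize to voxel centres,
    as it would on a scanner with no reconstruction blur."""
    s = spec.spacing
    n = _SUPERSAMPLE
    offs = (np.arange(n) + 0.5) / n - 0.5  # sub-offsets in voxel units
    shape = tuple(h - l for l, h in zip(lo_idx, hi_idx))
    base = [s * (np.arange(l, h)) for l, h in zip(lo_idx, hi_idx)]
    # voxel centre of index i is at i*spacing; sample around each centre
    sub = [np.add.outer(b, offs * s).ravel() for b in base]
    gx, gy, gz = np.meshgrid(sub[0], sub[1], sub[2], indexing="ij")
    inside = inside_fn(np.stack([gx, gy, gz], axis=-1)).astype(float)
    if spec.psf_sigma_mm > 0:
        sigma_cells = spec.psf_sigma_mm / (s / n)
        inside = ndimage.gaussian_filter(inside, sigma_cells, mode="constant")
    inside = inside.reshape(shape[0], n, shape[1], n, shape[2], n)
    return inside.mean(axis=(1, 3, 5))


def _paint(vol, spec: PhantomSpec, lo, hi, occ, level):
    """Add a peak-normalized blurred-occupancy patch at ``level`` contrast,
    on top of the underlying tissue: the local intensity excess stays
    proportional to the PSF-blurred occupancy, whose first moment is the
    object's exact centre."""
    peak = occ.max()
    if peak <= 0:
        return
    ints = spec.intensities
    patch = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    patch += (occ / peak) * (level - ints.soft_tissue)


def _bounds(spec: PhantomSpec, center, pad_mm):
    lo = np.floor((np.asarray(center) - pad_mm) / spec.spacing).astype(int)
    hi = np.ceil((np.asarray(center) + pad_mm) / spec.spacing).astype(int) + 1
    clipped = bool(np.any(lo < 0) or np.any(hi > np.asarray(spec.shape)))
    lo = np.clip(lo, 0, np.asarray(spec.shape))
    hi = np.clip(hi, 0, np.asarray(spec.shape))
    return lo, hi, clipped


def _render_sphere(vol, spec, center, radius, level) -> bool:
    lo, hi, clipped = _bounds(spec, center,
                              radius + spec.spacing + 3 * spec.psf_sigma_mm)
    if np.any(hi - lo <= 0):
        return True

    def inside(p):
        return np.linalg.norm(p - center, axis=-1) <= radius

    occ = _occupancy(spec, lo, hi, inside)
    _paint(vol, spec, lo, hi, occ, level)
    return clipped


def _render_cylinder(vol, spec, p0, p1, radius, level) -> bool:
    """Finite cylinder from p0 to p1 (mm)."""
    center = (np.asarray(p0) + np.asarray(p1)) / 2.0
    axis = np.asarray(p1, float) - np.asarray(p0, float)
    length = np.linalg.norm(axis)
    if length <= 0:
        return _render_sphere(vol, spec, center, radius, level)
    u = axis / length
    pad = length / 2.0 + radius + spec.spacing + 3 * spec.psf_sigma_mm
    lo, hi, clipped = _bounds(spec, center, pad)
    if np.any(hi - lo <= 0):
        return True

    def inside(p):
        d = p - center
        along = d @ u
        rad2 = np.sum(d * d, axis=-1) - along ** 2
        return (np.abs(along) <= length / 2.0) & (rad2 <= radius ** 2)

    occ = _occupancy(spec, lo, hi, inside)
    _paint(vol, spec, lo, hi, occ, level)
    return clipped


def implant_seeds(phantom: Phantom, plan, placement_noise_sd: float = 0.0,
                  rng_seed: int = 0) -> Phantom:
    """Render the plan's seeds into a copy of the phantom.

    Each seed is a metal cylinder of the seed model's physical dimensions at
    its planned centre plus (optionally) an isotropic Gaussian placement
    offset; the realized post-noise centres are recorded in the truth list.
    Seeds pushed (partly) out of the volume are clipped and flagged.
    """
    out = phantom.copy()
    spec = phantom.spec
    rng = np.random.default_rng(rng_seed)
    seed = plan.seed_model
    half = seed.physical_length_mm / 2.0
    radius = seed.physical_diameter_mm / 2.0
    direction = plan.template_pose.normal
    level = spec.intensities.metal
    for p in plan.seed_positions:
        c = np.asarray(p, float)
        if placement_noise_sd > 0:
            c = c + rng.normal(0.0, placement_noise_sd, size=3)
        clipped = _render_cylinder(out.volume, spec, c - half * direction,
                                   c + half * direction, radius, level)
        out.truth.append(TruthObject("seed", c, direction=direction,
                                     size_mm=seed.physical_length_mm,
                                     clipped=clipped))
    return out


def implant_needles(phantom: Phantom, paths, radius_mm: float = 0.75,
                    shaft_overhang_mm: float = 25.0) -> Phantom:
    """Render needle shafts (entry side extended by the overhang) to tips."""
    out = phantom.copy()
    for path in paths:
        p1 = path.tip
        p0 = path.entry - shaft_overhang_mm * path.direction
        clipped = _render_cylinder(out.volume, phantom.spec, p0, p1, radius_mm,
                                   phantom.spec.intensities.metal)
        out.truth.append(TruthObject("needle", p1, direction=path.direction,
                                     size_mm=float(np.linalg.norm(p1 - p0)),
                                     clipped=clipped))
    return out


# ------------------------------------------------------------------
# detection

@dataclass(frozen=True)
class DetectedObject:
    kind: str                   # 'seed' | 'marker' | 'needle_tip'
    center: np.ndarray          # intensity-weighted centroid, mm
    voxel_count: int
    principal_axis: np.ndarray | None = None
    tip: np.ndarray | None = None  # needles only


@dataclass
class DetectionResult:
    objects: list

    def of_kind(self, kind: str) -> list:
        return [o for o in self.objects if o.kind == kind]

    def centers(self, kind: str | None = None) -> np.ndarray:
        objs = self.objects if kind is None else self.of_kind(kind)
        if not objs:
            return np.empty((0, 3))
        return np.array([o.center for o in objs])


_26CONN = np.ones((3, 3, 3), dtype=int)


def detect_objects(volume: np.ndarray, spacing: float = 1.0,
                   intensity_threshold: float = 1850.0,
                   baseline: float = 100.0,
                   min_voxels: int = 1, max_voxels: int | None = None,
                   seed_max_mass_voxels: float = 18.0,
                   needle_min_elongation: float = 3.0) -> DetectionResult:
    """Threshold + 26-connected labeling + size-based classification.

    Components are classified by size: those whose integrated
    partial-volume mass (sum of intensity excess over ``baseline``,
    normalized to the component peak, in voxel equivalents) is at most
    ``seed_max_mass_voxels`` are seed-sized; of the larger ones, rod-like
    components (weighted principal-axis elongation >=
    ``needle_min_elongation``) are needles (reported as ``needle_tip``
    with the tip estimated from the weighted principal axis) and compact
    ones are marker-sized.
    Mass is used rather than the raw voxel count because a thin seed
    centred on a voxel corner spreads its occupancy over up to ~12-16
    voxels while its mass stays geometry-stable.  Centroids are
    intensity-above-baseline weighted over the component dilated by one
    voxel, which undoes the partial-volume quantization of thin metal
    objects.  Objects are returned in deterministic (z, y, x)
    lexicographic centroid order.
    """
    labels, n = ndimage.label(volume >= intensity_threshold, structure=_26CONN)
    objs: list[DetectedObject] = []
    if n == 0:
        return DetectionResult(objs)
    shape = np.asarray(volume.shape)
    for lab in range(1, n + 1):
        comp = labels == lab
        count = int(comp.sum())
        if count < min_voxels or (max_voxels is not None and count > max_voxels):
            continue
        support = ndimage.binary_dilation(comp, structure=_26CONN)
        w = np.where(support, np.maximum(volume - baseline, 0.0), 0.0)
        total = w.sum()
        if total <= 0:
            continue
        idx = np.argwhere(support)
        ww = w[support]
        centroid_vox = (idx * ww[:, None]).sum(axis=0) / total
        center = centroid_vox * spacing
        axis, tip = None, None
        mass = total / ww.max()  # peak-normalized mass in voxel equivalents
        d = (idx - centroid_vox) * spacing
        cov = (d * ww[:, None]).T @ d / total
        evals, evecs = np.linalg.eigh(cov)
        elongation = np.sqrt(evals[-1] / max(evals[-2], 1e-12))
        if mass <= seed_max_mass_voxels:
            kind = "seed"
        elif elongation >= needle_min_elongation:
            kind = "needle_tip"
            axis = evecs[:, -1]
            if axis[2] < 0 or (axis[2] == 0 and axis.sum() < 0):
                axis = -axis  # orient along +z (insertion direction)
            # rod model: axial variance = L^2/12 -> tip at centroid + L/2
            half_len = np.sqrt(12.0 * evals[-1]) / 2.0
            tip = center + half_len * axis
        else:
            kind = "marker"
        objs.append(DetectedObject(kind, center, count, axis, tip))
    objs.sort(key=lambda o: (round(o.center[2], 6), round(o.center[1], 6),
                             round(o.center[0], 6)))
    return DetectionResult(objs)


@dataclass
class MatchResult:
    pairs: list                 # (planned_index, detected_index, distance_mm)
    unmatched_planned: list
    unmatched_detected: list

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])


def match_objects(planned, detected, max_distance: float = 5.0) -> MatchResult:
    """Mutual-nearest-neighbour pairing under a distance cap; each point is
    used at most once; deterministic (shortest pairs first)."""
    p = np.atleast_2d(np.asarray(planned, float)) if len(planned) else np.empty((0, 3))
    d = np.atleast_2d(np.asarray(detected, float)) if len(detected) else np.empty((0, 3))
    if p.size == 0 or d.size == 0:
        return MatchResult([], list(range(p.shape[0])), list(range(d.shape[0])))
    dist = np.linalg.norm(p[:, None, :] - d[None, :, :], axis=2)
    pairs = []
    used_p: set[int] = set()
    used_d: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > max_distance:
            break
        if i in used_p or j in used_d:
            continue
        # mutual nearest among the remaining points
        pairs.append((int(i), int(j), float(dist[i, j])))
        used_p.add(int(i))
        used_d.add(int(j))
    return MatchResult(pairs,
                       [i for i in range(p.shape[0]) if i not in used_p],
                       [j for j in range(d.shape[0]) if j not in used_d])
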