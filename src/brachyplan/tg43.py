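"""TG-43 1-D (point-source) dose engine for permanently implanted I-125 seeds.

Dose rate around a single seed follows the AAPM TG-43 1-D formalism

    Ddot(r) = S_K * Lambda * (r0 / r)^2 * g(r) * phi_an(r),   r0 = 1 cm,

with air-kerma strength S_K in U (uGy m^2/h), dose-rate constant Lambda in
cGy/h/U, radial dose function g(r) and 1-D anisotropy factor phi_an(r)
tabulated against radial distance in cm.  A permanent implant accumulates

    D(t) = Ddot(0) * tau * (1 - exp(-t / tau)),   tau = T_half / ln 2,

which for I-125 (T_half = 59.4 d) integrates to Ddot(0) x 2056.9 h at
infinite horizon.  Internal rates are cGy/h; accumulated doses are reported
in Gy.  Grid distances are voxel-centre to seed-centre.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MCI_TO_BQ",
    "SK_PER_MCI_I125",
    "SeedSource",
    "GridSpec",
    "DoseGrid",
    "default_seed",
    "activity_to_bq",
    "activity_to_air_kerma_strength",
    "radial_dose",
    "anisotropy_factor",
    "dose_rate_at",
    "cumulative_dose",
    "dose_grid_from_seeds",
]

MCI_TO_BQ = 3.7e7          # Bq per mCi, definitional
SK_PER_MCI_I125 = 1.270    # U per mCi apparent activity, I-125 default
I125_HALF_LIFE_DAYS = 59.4

# Bundled 1-D dataset representative of published consensus-style data for a
# low-energy I-125 seed: near-exponential g(r) in water, slowly varying
# phi_an(r).  Fully overridable via SeedSource/from_json.
_G_KNOTS_CM = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
_G_VALUES = np.array([1.055, 1.000, 0.919, 0.839, 0.691, 0.563,
                      0.457, 0.369, 0.297, 0.238, 0.191, 0.153])
_PHI_KNOTS_CM = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0])
_PHI_VALUES = np.array([0.944, 0.941, 0.940, 0.939, 0.938, 0.937, 0.936, 0.935])


def activity_to_bq(apparent_activity_mci: float) -> float:
    """Apparent activity in mCi -> Bq (1 mCi = 3.7e7 Bq)."""
    if not np.isfinite(apparent_activity_mci) or apparent_activity_mci < 0:
        raise ValueError("activity must be non-negative")
    return apparent_activity_mci * MCI_TO_BQ


def activity_to_air_kerma_strength(apparent_activity_mci: float,
                                   conversion: float = SK_PER_MCI_I125) -> float:
    """Apparent activity in mCi -> air-kerma strength S_K in U."""
    if not np.isfinite(apparent_activity_mci) or apparent_activity_mci < 0:
        raise ValueError("activity must be non-negative")
    return apparent_activity_mci * conversion


def _validate_table(r, v, name):
    r = np.asarray(r, dtype=float)
    v = np.asarray(v, dtype=float)
    if r.ndim != 1 or r.shape != v.shape or r.size < 2:
        raise ValueError(f"{name} must be two equal-length 1-D arrays (>=2 knots)")
    if np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError(f"{name} radii must be positive and strictly increasing")
    if np.any(v <= 0):
        raise ValueError(f"{name} values must be strictly positive")
    return r, v


@dataclass(frozen=True)
class SeedSource:
    """TG-43 parameters of one I-125 seed model."""

    air_kerma_strength: float                 # U
    dose_rate_constant: float                 # cGy/h/U
    radial_dose_table: tuple                  # (r_cm, g(r)) arrays
    anisotropy_table: tuple                   # (r_cm, phi_an(r)) arrays
    half_life_days: float = I125_HALF_LIFE_DAYS
    physical_length_mm: float = 3.0           # silver-rod core length
    physical_diameter_mm: float = 0.5
    name: str = "I125-generic"

    def __post_init__(self):
        if self.air_kerma_strength <= 0 or self.dose_rate_constant <= 0 \
                or self.half_life_days <= 0 or self.physical_length_mm <= 0 \
                or self.physical_diameter_mm <= 0:
            raise ValueError("seed parameters must be strictly positive")
        gr, gv = _validate_table(*self.radial_dose_table, "radial_dose_table")
        ar, av = _validate_table(*self.anisotropy_table, "anisotropy_table")
        object.__setattr__(self, "radial_dose_table", (gr, gv))
        object.__setattr__(self, "anisotropy_table", (ar, av))

    def with_strength(self, air_kerma_strength: float) -> "SeedSource":
        return replace(self, air_kerma_strength=air_kerma_strength)

    def to_json(self, path) -> None:
        gr, gv = self.radial_dose_table
        ar, av = self.anisotropy_table
        d = {
            "name": self.name,
            "air_kerma_strength_U": self.air_kerma_strength,
            "dose_rate_constant_cGy_per_h_per_U": self.dose_rate_constant,
            "half_life_days": self.half_life_days,
            "physical_length_mm": self.physical_length_mm,
            "physical_diameter_mm": self.physical_diameter_mm,
            "radial_dose_r_cm": list(map(float, gr)),
            "radial_dose_g": list(map(float, gv)),
            "anisotropy_r_cm": list(map(float, ar)),
            "anisotropy_phi": list(map(float, av)),
        }
        with open(path, "w") as f:
            json.dump(d, f, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SeedSource":
        with open(path) as f:
            d = json.load(f)
        return cls(
            air_kerma_strength=d["air_kerma_strength_U"],
            dose_rate_constant=d["dose_rate_constant_cGy_per_h_per_U"],
            radial_dose_table=(d["radial_dose_r_cm"], d["radial_dose_g"]),
            anisotropy_table=(d["anisotropy_r_cm"], d["anisotropy_phi"]),
            half_life_days=d.get("half_life_days", I125_HALF_LIFE_DAYS),
            physical_length_mm=d.get("physical_length_mm", 3.0),
            physical_diameter_mm=d.get("physical_diameter_mm", 0.5),
            name=d.get("name", "I125-custom"),
        )


def default_seed(activity_mci: float = 0.7,
                 dose_rate_constant: float = 0.965) -> SeedSource:
    """Default I-125 seed; strength from apparent activity (default 0.7 mCi)."""
    return SeedSource(
        air_kerma_strength=activity_to_air_kerma_strength(activity_mci),
        dose_rate_constant=dose_rate_constant,
        radial_dose_table=(_G_KNOTS_CM, _G_VALUES),
        anisotropy_table=(_PHI_KNOTS_CM, _PHI_VALUES),
    )


def _log_linear(r, knots, values):
    """Interpolate log(value) linearly in r; clamp below the first knot,
    extrapolate above the last from the final two knots (floored at 0)."""
    r = np.asarray(r, dtype=float)
    logv = np.log(values)
    out = np.exp(np.interp(r, knots, logv))
    # np.interp clamps both ends; redo the upper end by extrapolation
    hi = r > knots[-1]
    if np.any(hi):
        slope = (logv[-1] - logv[-2]) / (knots[-1] - knots[-2])
        out = np.where(hi, np.exp(logv[-1] + slope * (r - knots[-1])), out)
    return out


def radial_dose(seed: SeedSource, r) -> np.ndarray | float:
    """Radial dose function g(r), r in cm (g(1 cm) = 1 by normalization)."""
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("r must be positive and finite (cm)")
    out = _log_linear(r, *seed.radial_dose_table)
    return float(out) if out.ndim == 0 else out


def anisotropy_factor(seed: SeedSource, r) -> np.ndarray | float:
    """1-D anisotropy factor phi_an(r), r in cm; same interpolation as g(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("r must be positive and finite (cm)")
    out = _log_linear(r, *seed.anisotropy_table)
    return float(out) if out.ndim == 0 else out


def dose_rate_at(seed: SeedSource, r, min_radius_cm: float = 0.05):
    """TG-43 1-D dose rate at radial distance r (cm), in cGy/h.

    r is clamped to ``min_radius_cm`` before evaluation to avoid the
    inverse-square singularity inside the capsule.
    """
    r = np.asarray(r, dtype=float)
    if min_radius_cm > 0:
        r = np.maximum(r, min_radius_cm)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("r must be positive (cm); set min_radius_cm > 0 to clamp")
    rate = (seed.air_kerma_strength * seed.dose_rate_constant / r ** 2
            * radial_dose(seed, r) * anisotropy_factor(seed, r))
    return float(rate) if np.ndim(rate) == 0 else rate


def cumulative_dose(initial_rate_cgy_per_h, half_life_days: float,
                    horizon_days: float = math.inf):
    """Accumulated dose in Gy of a decaying source, closed form.

    D = Ddot0 * tau * (1 - exp(-t/tau)), tau = T_half/ln2 in hours;
    infinite horizon gives the full permanent-implant dose Ddot0 * tau.
    """
    if not half_life_days > 0:
        raise ValueError("half_life_days must be positive")
    if not horizon_days >= 0:
        raise ValueError("horizon_days must be non-negative (or inf)")
    rate = np.asarray(initial_rate_cgy_per_h, dtype=float)
    tau_h = half_life_days * 24.0 / math.log(2.0)
    frac = 1.0 if math.isinf(horizon_days) else -math.expm1(-horizon_days * 24.0 / tau_h)
    dose = rate * tau_h * frac / 100.0  # cGy -> Gy
    return float(dose) if dose.ndim == 0 else dose


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel lattice: origin (centre of voxel [0,0,0]), spacing
    per axis (mm), and voxel counts."""

    origin: tuple = (0.0, 0.0, 0.0)
    spacing: tuple = (1.0, 1.0, 1.0)
    shape: tuple = (64, 64, 64)

    def __post_init__(self):
        o = tuple(float(v) for v in self.origin)
        s = tuple(float(v) for v in self.spacing)
        n = tuple(int(v) for v in self.shape)
        if len(o) != 3 or len(s) != 3 or len(n) != 3:
            raise ValueError("origin, spacing, shape must each have 3 entries")
        if any(x <= 0 for x in s) or any(x < 1 for x in n):
            raise ValueError("spacing must be positive and shape >= 1 per axis")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", s)
        object.__setattr__(self, "shape", n)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes_mm(self):
        return tuple(self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
                     for k in range(3))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates in C order."""
        ax, ay, az = self.axes_mm()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a voxel lattice."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != tuple(self.spec.shape):
            raise ValueError(f"values shape {v.shape} != grid shape {self.spec.shape}")
        if np.any(v < 0):
            raise ValueError("dose values must be non-negative")
        self.values = v


def dose_grid_from_seeds(seeds, grid: GridSpec,
                         horizon_days: float = math.inf,
                         min_radius_cm: float = 0.05) -> DoseGrid:
    """Superpose the permanent-implant dose of every seed onto a grid.

    ``seeds`` is a sequence of (position_mm, SeedSource) pairs (a bare
    position sequence plus a single ``SeedSource`` via
    ``[(p, seed) for p in positions]``).  Voxel dose is the sum over seeds
    of the decay-integrated TG-43 point-source dose at the voxel-centre to
    seed-centre distance; seeds outside the grid still contribute.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    centers = grid.voxel_centers()
    total = np.zeros(centers.shape[0])
    for pos, seed in seeds:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad seed position {pos}")
        r_cm = np.linalg.norm(centers - pos, axis=1) / 10.0
        rate = dose_rate_at(seed, r_cm, min_radius_cm=min_radius_cm)
        total += cumulative_dose(rate, seed.half_life_days, horizon_days)
    return DoseGrid(grid, total.reshape(grid.shape))
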