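"""DVH construction and scalar plan dosimetry: D_x, V_x, CI, HI, and the
mean +/- sd and t-test statistics used to compare pre- and postoperative
plans.

Conventions
-----------
* D_x is the dose received by at least x% of the structure, found on the
  cumulative DVH with linear interpolation between bins; D100 is the
  minimum structure dose.
* V_d is the fraction of the structure receiving at least dose d.
* CI = (V_T,ref / V_T) * (V_T,ref / V_ref): V_T the target volume, V_ref the
  volume enclosed by the prescription isodose, V_T,ref their intersection,
  all by voxel counting on the shared lattice.
* HI = (D2 - D98) / D_ref * 100 (percent).
* The default between-group test is an unpaired two-tailed Student t with
  pooled variance (paired and Welch variants by flag); significance at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tg43 import DoseGrid, GridSpec

__all__ = [
    "StructureMask",
    "DVHCurve",
    "PlanMetrics",
    "TTestResult",
    "ComparisonReport",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "conformity_index",
    "homogeneity_index",
    "plan_metrics",
    "mean_sd",
    "two_sample_ttest",
    "compare_plans",
]

DEFAULT_BIN_WIDTH_GY = 0.1
_GEOM_TOL = 1e-6


@dataclass
class StructureMask:
    """Boolean voxel membership of one structure (e.g. the GTV) on a grid."""

    spec: GridSpec
    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.dtype != bool:
            m = m.astype(bool)
        if m.shape != tuple(self.spec.shape):
            raise ValueError(f"mask shape {m.shape} != grid shape {self.spec.shape}")
        self.mask = m

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spec.voxel_volume_mm3

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


def _check_aligned(dose: DoseGrid, mask: StructureMask):
    a, b = dose.spec, mask.spec
    if a.shape != b.shape or \
            max(abs(x - y) for x, y in zip(a.origin, b.origin)) > _GEOM_TOL or \
            max(abs(x - y) for x, y in zip(a.spacing, b.spacing)) > _GEOM_TOL:
        raise ValueError("dose grid and structure mask geometries are not aligned")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= bin dose."""

    dose_bins: np.ndarray          # Gy, ascending, starting at 0
    cumulative_fraction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose_bins, float)
        f = np.asarray(self.cumulative_fraction, float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("dose_bins and cumulative_fraction must be equal-length 1-D")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose_bins must be strictly ascending")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("cumulative_fraction must be non-increasing")
        if abs(f[0] - 1.0) > 1e-12:
            raise ValueError("cumulative_fraction must start at 1.0 (everything gets >= 0)")
        object.__setattr__(self, "dose_bins", d)
        object.__setattr__(self, "cumulative_fraction", f)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_Gy": self.dose_bins,
                             "fraction_ge": self.cumulative_fraction})


def compute_dvh(dose: DoseGrid, mask: StructureMask,
                bin_width: float = DEFAULT_BIN_WIDTH_GY) -> DVHCurve:
    """Cumulative ('receives at least') DVH over the masked voxels."""
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    _check_aligned(dose, mask)
    if mask.voxel_count == 0:
        raise ValueError("structure mask is empty")
    doses = np.sort(dose.values[mask.mask].ravel())
    n = doses.size
    top = doses[-1] + 2 * bin_width  # extend past the max so the curve reaches 0
    bins = np.arange(0.0, top, bin_width)
    frac = 1.0 - np.searchsorted(doses, bins, side="left") / n
    return DVHCurve(bins, frac)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """D_x: the largest dose received by at least x% of the structure (Gy)."""
    if not 0 < x_percent <= 100:
        raise ValueError("x must be in (0, 100]")
    q = x_percent / 100.0
    f = dvh.cumulative_fraction
    d = dvh.dose_bins
    ge = np.nonzero(f >= q - 1e-15)[0]
    if ge.size == 0:
        return 0.0
    i = ge[-1]
    if i == d.size - 1 or f[i] <= q + 1e-15:
        return float(d[i])
    # interpolate the crossing of level q between bins i and i+1
    return float(d[i] + (f[i] - q) / (f[i] - f[i + 1]) * (d[i + 1] - d[i]))


def volume_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """V_d: interpolated fraction of the structure receiving >= d Gy."""
    if not d_gy >= 0:
        raise ValueError("dose must be non-negative")
    return float(np.interp(d_gy, dvh.dose_bins, dvh.cumulative_fraction,
                           right=0.0))


def conformity_index(v_t: float, v_ref: float, v_t_ref: float) -> float:
    """CI = (V_T,ref/V_T) * (V_T,ref/V_ref); 1 only for perfect conformity."""
    if not (v_t > 0 and v_ref > 0):
        raise ValueError("V_T and V_ref must be positive")
    if v_t_ref < 0 or v_t_ref > min(v_t, v_ref) * (1 + 1e-12):
        raise ValueError("V_T,ref must lie in [0, min(V_T, V_ref)]")
    return (v_t_ref / v_t) * (v_t_ref / v_ref)


def homogeneity_index(d2: float, d98: float, d_ref: float) -> float:
    """HI = (D2 - D98) / D_ref * 100, in percent."""
    if not d_ref > 0:
        raise ValueError("D_ref must be positive")
    if d2 < d98:
        raise ValueError("D2 must be >= D98")
    return (d2 - d98) / d_ref * 100.0


@dataclass(frozen=True)
class PlanMetrics:
    """Scalar dosimetry of one plan for one target structure."""

    d90: float      # Gy
    d100: float     # Gy (minimum structure dose)
    d2: float       # Gy
    d98: float      # Gy
    v90: float      # fractions of the structure volume
    v100: float
    v150: float
    v200: float
    ci: float       # unitless
    hi: float       # percent
    prescription_gy: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("d90", "d100", "d2", "d98", "v90", "v100", "v150", "v200",
                 "ci", "hi", "prescription_gy")}

    # Table-style percent-of-prescription views
    @property
    def d90_pct(self) -> float:
        return self.d90 / self.prescription_gy * 100.0

    @property
    def d100_pct(self) -> float:
        return self.d100 / self.prescription_gy * 100.0


def plan_metrics(dose: DoseGrid, mask: StructureMask, prescription_gy: float,
                 bin_width: float = DEFAULT_BIN_WIDTH_GY) -> PlanMetrics:
    """All scalar metrics of a dose distribution against a target mask."""
    if not prescription_gy > 0:
        raise ValueError("prescription must be positive")
    _check_aligned(dose, mask)
    dvh = compute_dvh(dose, mask, bin_width=bin_width)
    masked = dose.values[mask.mask]
    d100 = float(masked.min())
    d2 = dose_at_volume(dvh, 2)
    d98 = dose_at_volume(dvh, 98)
    vv = mask.voxel_volume_mm3
    v_t = mask.voxel_count * vv
    ref_region = dose.values >= prescription_gy
    v_ref = float(ref_region.sum()) * vv
    v_t_ref = float((ref_region & mask.mask).sum()) * vv
    ci = conformity_index(v_t, v_ref, v_t_ref) if v_ref > 0 else 0.0
    return PlanMetrics(
        d90=dose_at_volume(dvh, 90),
        d100=d100,
        d2=d2,
        d98=d98,
        v90=volume_at_dose(dvh, 0.9 * prescription_gy),
        v100=volume_at_dose(dvh, prescription_gy),
        v150=volume_at_dose(dvh, 1.5 * prescription_gy),
        v200=volume_at_dose(dvh, 2.0 * prescription_gy),
        ci=ci,
        hi=homogeneity_index(d2, d98, prescription_gy),
        prescription_gy=prescription_gy,
    )


def mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation.

    sd is None for a single value; rounding to printed precision is left to
    the report layer.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("mean_sd requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    m = float(v.mean())
    return m, (float(v.std(ddof=1)) if v.size > 1 else None)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool  # at the 0.05 level


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     paired: bool = False, equal_var: bool = True) -> TTestResult:
    """Two-tailed t-test between two samples (Student pooled by default)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if np.allclose(a, b):
            return TTestResult(0.0, 1.0, False)
        res = stats.ttest_rel(a, b)
    else:
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
            return TTestResult(0.0, 1.0, False)  # degenerate constant groups
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       bool(res.pvalue < 0.05))


_COMPARE_METRICS = ("ci", "hi", "d100", "d90", "v100", "v90")


@dataclass
class ComparisonReport:
    """Per-metric pre/post group means +/- sd and t-test results."""

    table: pd.DataFrame          # rows: metric; cols: pre_mean, pre_sd, post_mean, post_sd, t, p
    pre: list
    post: list

    def to_json_dict(self) -> dict:
        return {m: {k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()}
                for m, row in self.table.iterrows()}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="metric")


def compare_plans(pre: Sequence[PlanMetrics], post: Sequence[PlanMetrics],
                  metrics: Sequence[str] = _COMPARE_METRICS,
                  paired: bool = False) -> ComparisonReport:
    """Aggregate per-case pre/post metrics the way Table-3-style reports do."""
    pre = list(pre)
    post = list(post)
    if len(pre) != len(post):
        raise ValueError("pre and post case lists must have equal length")
    if not pre:
        raise ValueError("empty case lists")
    rows = {}
    for m in metrics:
        va = [getattr(p, m) for p in pre]
        vb = [getattr(p, m) for p in post]
        ma, sa = mean_sd(va)
        mb, sb = mean_sd(vb)
        if len(va) >= 2:
            tt = two_sample_ttest(va, vb, paired=paired)
            t, p = tt.t, tt.p
        else:
            t, p = np.nan, np.nan
        rows[m] = {"pre_mean": ma, "pre_sd": sa if sa is not None else np.nan,
                   "post_mean": mb, "post_sd": sb if sb is not None else np.nan,
                   "t": t, "p": p}
    return ComparisonReport(pd.DataFrame(rows).T, pre, post)
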