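"""DVH and scalar dosimetry: counting/order-statistic oracles on random
grids, hand-formula CI/HI, and the printed-table statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.testing import assert_allclose
from scipy import integrate, special

from brachyplan.dosimetry import (DVHCurve, StructureMask, compare_plans,
                                  compute_dvh, conformity_index, dose_at_volume,
                                  homogeneity_index, mean_sd, plan_metrics,
                                  two_sample_ttest, volume_at_dose)
from brachyplan.tg43 import DoseGrid, GridSpec


def _grid_and_mask(doses):
    """Pack a 1-D dose list into a (n,1,1) grid with an all-true mask."""
    doses = np.asarray(doses, float)
    spec = GridSpec((0, 0, 0), (1, 1, 1), (doses.size, 1, 1))
    return (DoseGrid(spec, doses.reshape(-1, 1, 1)),
            StructureMask(spec, np.ones((doses.size, 1, 1), bool)))


def test_dvh_uniform_dose_step():
    dose, mask = _grid_and_mask([5.0] * 32)
    dvh = compute_dvh(dose, mask, bin_width=0.5)
    assert dvh.cumulative_fraction[0] == 1.0
    assert volume_at_dose(dvh, 5.0) == pytest.approx(1.0)
    assert volume_at_dose(dvh, 5.6) == pytest.approx(0.0)
    for x in (2, 50, 90, 98):
        assert dose_at_volume(dvh, x) == pytest.approx(5.0, abs=0.5)


def test_dvh_two_voxel_enumerable():
    dose, mask = _grid_and_mask([1.0, 3.0])
    dvh = compute_dvh(dose, mask, bin_width=0.1)
    assert volume_at_dose(dvh, 0.0) == 1.0
    assert volume_at_dose(dvh, 1.0) == pytest.approx(1.0)
    assert volume_at_dose(dvh, 2.0) == pytest.approx(0.5)
    assert volume_at_dose(dvh, 3.0) == pytest.approx(0.5)
    assert dose_at_volume(dvh, 98) == pytest.approx(1.0, abs=0.1)
    assert dose_at_volume(dvh, 2) == pytest.approx(3.0, abs=0.1)


def test_dvh_counting_oracle_random_grid(rng):
    """DVH fractions equal direct >= counting at every bin edge."""
    doses = rng.gamma(2.0, 5.0, size=1000)
    dose, mask = _grid_and_mask(doses)
    dvh = compute_dvh(dose, mask, bin_width=0.25)
    direct = np.array([(doses >= b).mean() for b in dvh.dose_bins])
    assert_allclose(dvh.cumulative_fraction, direct, atol=1e-12)
    assert np.all(np.diff(dvh.cumulative_fraction) <= 1e-12)
    assert dvh.cumulative_fraction[-1] == 0.0


def test_dose_at_volume_order_statistic_oracle(rng):
    """D_x matches sorting the voxel doses and indexing at the percentile,
    to within one DVH bin."""
    doses = np.sort(rng.uniform(0, 50, size=400))
    dose, mask = _grid_and_mask(doses)
    bw = 0.05
    dvh = compute_dvh(dose, mask, bin_width=bw)
    n = doses.size
    for x in (2, 10, 50, 90, 98):
        # largest dose with at least x% of voxels at or above it
        k = n - int(math.ceil(x / 100.0 * n - 1e-9))
        oracle = doses[min(k, n - 1)]
        assert dose_at_volume(dvh, x) == pytest.approx(oracle, abs=2 * bw)


def test_dvh_bin_halving_stability(rng):
    doses = rng.uniform(0, 20, size=500)
    dose, mask = _grid_and_mask(doses)
    coarse = compute_dvh(dose, mask, bin_width=0.4)
    fine = compute_dvh(dose, mask, bin_width=0.2)
    for x in (10, 50, 90):
        assert abs(dose_at_volume(coarse, x) - dose_at_volume(fine, x)) <= 0.4


def test_dvh_inverse_relationship(rng):
    doses = rng.uniform(0, 30, size=300)
    dose, mask = _grid_and_mask(doses)
    dvh = compute_dvh(dose, mask, bin_width=0.1)
    for x in (20, 60, 95):
        v = volume_at_dose(dvh, dose_at_volume(dvh, x))
        assert v >= x / 100.0 - 0.01


def test_dvh_rejects_misaligned_geometry():
    dose, _ = _grid_and_mask([1.0, 2.0])
    other = StructureMask(GridSpec((5, 0, 0), (1, 1, 1), (2, 1, 1)),
                          np.ones((2, 1, 1), bool))
    with pytest.raises(ValueError):
        compute_dvh(dose, other)


@pytest.mark.parametrize("vt, vref, vtref, expected", [
    (50.0, 50.0, 50.0, 1.0),
    (10.0, 20.0, 10.0, 0.5),
    (100.0, 90.0, 85.0, (85 / 100) * (85 / 90)),  # 0.8028
])
def test_conformity_index_hand_values(vt, vref, vtref, expected):
    assert conformity_index(vt, vref, vtref) == pytest.approx(expected)


def test_conformity_index_bounds_and_errors():
    with pytest.raises(ValueError):
        conformity_index(0.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        conformity_index(10.0, 10.0, 11.0)


@settings(derandomize=True, max_examples=200)
@given(st.floats(1, 1e3), st.floats(1, 1e3), st.floats(0, 1))
def test_conformity_index_formula_property(vt, vref, frac):
    vtref = frac * min(vt, vref)
    ci = conformity_index(vt, vref, vtref)
    assert 0.0 <= ci <= 1.0 + 1e-12
    assert ci == pytest.approx((vtref / vt) * (vtref / vref))


def test_homogeneity_index_hand_values():
    assert homogeneity_index(5.0, 5.0, 100.0) == 0.0
    assert homogeneity_index(105.0, 101.5, 100.0) == pytest.approx(3.5)
    assert homogeneity_index(105.0, 101.5, 200.0) == pytest.approx(1.75)
    with pytest.raises(ValueError):
        homogeneity_index(1.0, 2.0, 100.0)


def test_mean_sd_printed_rows():
    m, sd = mean_sd([0.72, 0.71, 0.77, 0.80, 0.53, 0.69])
    assert (round(m, 2), round(sd, 2)) == (0.70, 0.09)
    m, sd = mean_sd([0.95, 0.97, 0.95, 0.98, 0.95])
    assert (round(m, 3), round(sd, 3)) == (0.960, 0.014)
    assert mean_sd([2.0, 2.0, 2.0])[1] == 0.0
    assert mean_sd([7.0]) == (7.0, None)
    with pytest.raises(ValueError):
        mean_sd([])


def test_mean_sd_two_pass_oracle(rng):
    v = rng.normal(10, 3, size=97)
    m, sd = mean_sd(v)
    mo = float(np.sum(v)) / v.size
    sdo = math.sqrt(float(np.sum((v - mo) ** 2)) / (v.size - 1))
    assert m == pytest.approx(mo, abs=1e-12)
    assert sd == pytest.approx(sdo, abs=1e-12)


def _ttest_oracle(a, b):
    """Pooled-variance Student t with p by numerical integration of the
    t-density (independent of scipy.stats)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    c = math.exp(special.gammaln((df + 1) / 2) - special.gammaln(df / 2)) \
        / math.sqrt(df * math.pi)
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return t, 2 * tail


def test_ttest_identical_samples():
    r = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)
    assert not r.significant


def test_ttest_reproduces_printed_ci_p():
    r = two_sample_ttest([0.95, 0.97, 0.95, 0.98, 0.95],
                         [0.94, 0.94, 0.95, 0.97, 0.96])
    assert round(r.p, 2) == 0.38
    assert round(r.p, 3) == 0.380
    assert not r.significant


def test_ttest_matches_direct_formula_oracle(rng):
    for _ in range(10):
        a = rng.normal(0, 1, size=rng.integers(4, 30))
        b = rng.normal(0.5, 1.5, size=rng.integers(4, 30))
        r = two_sample_ttest(a, b)
        t0, p0 = _ttest_oracle(a, b)
        assert r.t == pytest.approx(t0, rel=1e-9)
        assert r.p == pytest.approx(p0, rel=1e-6)
    with pytest.raises(ValueError):
        two_sample_ttest([1.0], [1.0, 2.0])


def test_plan_metrics_uniform_dose_inside_mask():
    spec = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10))
    values = np.zeros((10, 10, 10))
    mask = np.zeros((10, 10, 10), bool)
    mask[2:8, 2:8, 2:8] = True
    values[mask] = 100.0
    m = plan_metrics(DoseGrid(spec, values), StructureMask(spec, mask), 100.0)
    assert m.v100 == pytest.approx(1.0)
    assert m.d90 == pytest.approx(100.0, abs=0.1)
    assert m.d100 == pytest.approx(100.0)
    assert m.ci == pytest.approx(1.0)  # reference region == target exactly
    assert m.hi == pytest.approx(0.0, abs=0.2)
    zero = plan_metrics(DoseGrid(spec, np.zeros((10, 10, 10))),
                        StructureMask(spec, mask), 100.0)
    assert zero.v100 == 0.0


def test_compare_plans_layout_and_permutation_invariance(rng):
    def metrics(ci, hi):
        from brachyplan.dosimetry import PlanMetrics
        return PlanMetrics(d90=100 + ci, d100=90, d2=110, d98=95,
                           v90=0.96, v100=0.95, v150=0.4, v200=0.1,
                           ci=ci, hi=hi, prescription_gy=100.0)
    pre = [metrics(c, h) for c, h in zip([0.95, 0.97, 0.95, 0.98, 0.95],
                                         [3.62, 3.43, 3.48, 3.59, 3.78])]
    post = [metrics(c, h) for c, h in zip([0.94, 0.94, 0.95, 0.97, 0.96],
                                          [3.38, 3.25, 3.55, 3.46, 3.42])]
    rep = compare_plans(pre, post)
    assert rep.table.loc["ci", "pre_mean"] == pytest.approx(0.960)
    assert rep.table.loc["ci", "post_mean"] == pytest.approx(0.952)
    assert rep.table.loc["hi", "pre_mean"] == pytest.approx(3.580)
    assert rep.table.loc["hi", "post_mean"] == pytest.approx(3.412)
    assert round(rep.table.loc["ci", "p"], 3) == 0.380
    # identical lists -> p = 1 everywhere defined
    same = compare_plans(pre, pre)
    assert same.table.loc["ci", "p"] == pytest.approx(1.0)
    # simultaneous case reordering leaves the report unchanged
    order = rng.permutation(5)
    rep2 = compare_plans([pre[i] for i in order], [post[i] for i in order])
    assert_allclose(rep2.table.values.astype(float),
                    rep.table.values.astype(float), rtol=1e-12)
    with pytest.raises(ValueError):
        compare_plans(pre, post[:3])
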