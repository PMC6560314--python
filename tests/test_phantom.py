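"""Synthetic phantom generation, seed rendering, detection, and matching."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from brachyplan.phantom import (Phantom, PhantomSpec, detect_objects,
                                generate_phantom, implant_needles,
                                implant_seeds, match_objects)

from conftest import make_single_seed_plan


SMALL = dict(shape=(32, 32, 32), tumor_center=(16.0, 16.0, 16.0),
             tumor_radii=(4.0, 4.0, 4.0))


def test_generate_phantom_deterministic():
    spec = PhantomSpec(**SMALL, noise_sd=25.0, rng_seed=42)
    a, b = generate_phantom(spec), generate_phantom(spec)
    assert np.array_equal(a.volume, b.volume)  # bit-identical
    c = generate_phantom(PhantomSpec(**SMALL, noise_sd=25.0, rng_seed=43))
    assert not np.array_equal(a.volume, c.volume)


def test_generate_phantom_no_noise_levels():
    spec = PhantomSpec(**SMALL)
    ph = generate_phantom(spec)
    ints = spec.intensities
    assert ph.volume[0, 0, 0] == ints.background
    assert ph.volume[3, 16, 16] == ints.soft_tissue
    assert ph.volume[16, 16, 16] == ints.tumor
    assert ph.tumor_mask().voxel_count > 0


def test_tumor_volume_matches_analytic_ellipsoid():
    """Default radii (12.5, 10, 12.5) mm give (4/3)*pi*r1*r2*r3 = 6.54 cm^3
    within 2% at 1 mm voxels."""
    spec = PhantomSpec(shape=(64, 64, 64), tumor_center=(32.0, 32.0, 32.0),
                       tumor_radii=(12.5, 10.0, 12.5))
    vol = generate_phantom(spec).tumor_mask().volume_cm3
    analytic = 4.0 / 3.0 * np.pi * 12.5 * 10.0 * 12.5 / 1000.0
    assert analytic == pytest.approx(6.545, abs=0.001)
    assert vol == pytest.approx(analytic, rel=0.02)


def test_phantom_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(shape=(8, 32, 32))
    with pytest.raises(ValueError):
        PhantomSpec(**dict(SMALL, tumor_radii=(30.0, 4.0, 4.0)))
    with pytest.raises(ValueError):
        PhantomSpec(**SMALL, marker_positions=((200.0, 0.0, 0.0),))


def test_rib_slab_rendering_with_gap():
    spec = PhantomSpec(**SMALL, rib_slabs=(
        __import__("brachyplan.phantom", fromlist=["RibSlab"]).RibSlab(
            position=6.0, thickness=2.0, gap_width=8.0),))
    ph = generate_phantom(spec)
    ints = spec.intensities
    assert ph.volume[5, 16, 7] == ints.bone        # in the slab, off the gap
    assert ph.volume[16, 16, 7] == ints.soft_tissue  # inside the gap
    assert ph.volume[5, 16, 20] == ints.soft_tissue  # outside the slab depth


def test_implant_seeds_zero_noise_truth_and_metal_maximum():
    spec = PhantomSpec(**SMALL)
    ph = generate_phantom(spec)
    plan = make_single_seed_plan((16.0, 16.0, 16.0))
    imp = implant_seeds(ph, plan, placement_noise_sd=0.0)
    seeds = [t for t in imp.truth if t.kind == "seed"]
    assert len(seeds) == 1
    assert_allclose(seeds[0].center, [16.0, 16.0, 16.0])
    assert not seeds[0].clipped
    # metal is the global intensity maximum (additive over the tissue level)
    assert imp.volume.max() >= spec.intensities.metal
    assert ph.volume.max() < spec.intensities.metal    # original untouched


def test_implant_seeds_noise_offsets_match_chi_mean(rng):
    """Isotropic Gaussian placement noise: mean 3-D offset = sd*sqrt(8/pi)."""
    spec = PhantomSpec(shape=(32, 32, 32), tumor_center=(16.0, 16.0, 16.0),
                       tumor_radii=(8.0, 8.0, 8.0))
    ph = generate_phantom(spec)
    plan = make_single_seed_plan((16.0, 16.0, 16.0))
    sd = 0.43
    offsets = []
    for k in range(400):
        imp = implant_seeds(ph, plan, placement_noise_sd=sd, rng_seed=k)
        c = [t for t in imp.truth if t.kind == "seed"][0].center
        offsets.append(np.linalg.norm(c - np.array([16.0, 16.0, 16.0])))
    mean = np.mean(offsets)
    analytic = sd * np.sqrt(8 / np.pi)
    se = sd * np.sqrt(3 - 8 / np.pi) / np.sqrt(len(offsets))
    assert abs(mean - analytic) < 3 * se


def test_detect_empty_volume_and_plain_phantom():
    spec = PhantomSpec(**SMALL)
    ph = generate_phantom(spec)
    det = detect_objects(ph.volume, spacing=spec.spacing)
    assert det.objects == []  # tumor/bone are below the metal threshold


def test_detect_single_seed_centroid_within_half_voxel():
    spec = PhantomSpec(**SMALL)
    ph = generate_phantom(spec)
    center = (16.3, 15.6, 16.8)  # deliberately off-lattice
    imp = implant_seeds(ph, make_single_seed_plan(center), 0.0)
    det = detect_objects(imp.volume, spacing=spec.spacing,
                         baseline=spec.intensities.tumor)
    seeds = det.of_kind("seed")
    assert len(seeds) == 1
    assert np.linalg.norm(seeds[0].center - np.array(center)) < spec.spacing / 2


def test_detect_six_seeds_one_to_one(rng):
    spec = PhantomSpec(shape=(48, 48, 48), tumor_center=(24.0, 24.0, 24.0),
                       tumor_radii=(10.0, 10.0, 10.0))
    ph = generate_phantom(spec)
    plan = make_single_seed_plan((24.0, 24.0, 24.0))
    centers = np.array([[20, 24, 20], [28, 24, 20], [24, 20, 26],
                        [24, 28, 26], [20, 24, 30], [28, 24, 30]], float)
    imp = ph
    for c in centers:
        imp = implant_seeds(imp, make_single_seed_plan(c), 0.0)
    det = detect_objects(imp.volume, spacing=spec.spacing,
                         baseline=spec.intensities.tumor)
    found = det.centers("seed")
    assert len(found) == 6
    match = match_objects(centers, found, max_distance=2.0)
    assert len(match.pairs) == 6
    assert np.all(match.distances < spec.spacing / 2)


def test_detection_ordering_deterministic():
    spec = PhantomSpec(**SMALL)
    ph = generate_phantom(spec)
    imp = implant_seeds(ph, make_single_seed_plan((12.0, 12.0, 20.0)), 0.0)
    imp = implant_seeds(imp, make_single_seed_plan((20.0, 20.0, 12.0)), 0.0)
    det = detect_objects(imp.volume, spacing=spec.spacing,
                         baseline=spec.intensities.tumor)
    zs = [o.center[2] for o in det.objects]
    assert zs == sorted(zs)  # lexicographic by z first


def test_needle_classification_and_tip():
    spec = PhantomSpec(shape=(48, 48, 48), tumor_center=(24.0, 24.0, 30.0),
                       tumor_radii=(6.0, 6.0, 6.0))
    ph = generate_phantom(spec)
    from brachyplan.geometry import NeedlePath
    needle = NeedlePath(np.array([24.0, 24.0, 4.0]),
                        np.array([0.0, 0.0, 1.0]), 28.0)
    imp = implant_needles(ph, [needle])
    det = detect_objects(imp.volume, spacing=spec.spacing,
                         baseline=spec.intensities.soft_tissue)
    tips = det.of_kind("needle_tip")
    assert len(tips) == 1
    assert np.linalg.norm(tips[0].tip - needle.tip) < 1.0
    assert abs(tips[0].principal_axis[2]) > 0.99


def test_match_objects_examples():
    m = match_objects([(0.0, 0.0, 0.0)], [(0.5, 0.5, 0.5)])
    assert len(m.pairs) == 1
    assert m.pairs[0][2] == pytest.approx(np.sqrt(0.75))
    same = match_objects([(1, 2, 3), (4, 5, 6)], [(1, 2, 3), (4, 5, 6)])
    assert all(d == 0 for _, _, d in same.pairs)
    empty = match_objects([(1, 2, 3)], [])
    assert empty.pairs == [] and empty.unmatched_planned == [0]
    far = match_objects([(0, 0, 0)], [(10, 10, 10)], max_distance=5.0)
    assert far.pairs == [] and far.unmatched_detected == [0]
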