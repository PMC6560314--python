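import numpy as np
import pytest

from brachyplan.dosimetry import StructureMask
from brachyplan.geometry import NeedlePath, TemplateModel, TemplatePose
from brachyplan.planning import ImplantPlan, PrescriptionConstraints
from brachyplan.tg43 import GridSpec, SeedSource, default_seed


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_table_seed():
    """Seed with g == phi == 1 everywhere: pure inverse-square source."""
    r = np.array([0.5, 1.0, 5.0, 10.0])
    ones = np.ones(4)
    return SeedSource(air_kerma_strength=1.0, dose_rate_constant=1.0,
                      radial_dose_table=(r, ones), anisotropy_table=(r, ones),
                      name="unit-tables")


@pytest.fixture
def sphere_target():
    """1-cm-diameter spherical target centred in a 40 mm cube at 1 mm voxels."""
    spec = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (40, 40, 40))
    ax = np.arange(40.0)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (gx - 20.0) ** 2 + (gy - 20.0) ** 2 + (gz - 20.0) ** 2 <= 25.0
    return StructureMask(spec, mask)


@pytest.fixture
def vertical_pose():
    return TemplatePose(np.array([20.0, 20.0, 2.0]),
                        np.array([0.0, 0.0, 1.0]),
                        np.array([1.0, 0.0, 0.0]))


def make_single_seed_plan(center, direction=(0.0, 0.0, 1.0),
                          activity_mci: float = 0.7) -> ImplantPlan:
    """Minimal one-needle, one-seed plan with the seed at ``center``."""
    center = np.asarray(center, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    depth = 20.0
    entry = center - depth * direction
    pose_origin = entry - 5.0 * direction
    in_plane = np.array([1.0, 0.0, 0.0])
    if abs(direction[0]) > 0.9:
        in_plane = np.array([0.0, 1.0, 0.0])
    in_plane = in_plane - np.dot(in_plane, direction) * direction
    in_plane /= np.linalg.norm(in_plane)
    pose = TemplatePose(pose_origin, direction, in_plane)
    template = TemplateModel()
    needle = NeedlePath(entry, direction, depth, entry_hole=(5, 5))
    return ImplantPlan(pose, template, (needle,), center.reshape(1, 3),
                       default_seed(activity_mci), PrescriptionConstraints())
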