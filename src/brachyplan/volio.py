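"""Volume I/O: NIfTI read/write with a JSON frame sidecar.

Volumes are stored with the affine diag(spacing) + origin translation, axis
order (x, y, z) matching the in-memory array storage order; the sidecar
records the frame convention so round-trips are unambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .tg43 import DoseGrid, GridSpec

__all__ = ["save_volume", "load_volume", "save_dose_grid", "load_dose_grid"]

_SIDECAR = {
    "frame": "right-handed, mm, origin at first voxel centre",
    "axis_order": "xyz (array storage order)",
    "format": "NIfTI-1",
}


def save_volume(path, values: np.ndarray, spec: GridSpec) -> None:
    affine = np.diag(list(spec.spacing) + [1.0])
    affine[:3, 3] = spec.origin
    nib.save(nib.Nifti1Image(np.asarray(values, np.float64), affine), str(path))
    sidecar = dict(_SIDECAR, spacing_mm=list(spec.spacing),
                   origin_mm=list(spec.origin), shape=list(spec.shape))
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[k, k]) for k in range(3))
    origin = tuple(float(aff[k, 3]) for k in range(3))
    values = np.asarray(img.dataobj, dtype=float)
    return values, GridSpec(origin, spacing, values.shape)


def save_dose_grid(path, dose: DoseGrid) -> None:
    save_volume(path, dose.values, dose.spec)


def load_dose_grid(path) -> DoseGrid:
    values, spec = load_volume(path)
    return DoseGrid(spec, values)
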