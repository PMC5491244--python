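"""Volume and table I/O.

Voxel volumes (material labels, masks, dose maps) are read and written
as NRRD through SimpleITK.  Internal arrays are indexed ``[x, y, z]``
(LPS); SimpleITK images are ``[z, y, x]``, so axes are transposed at
the boundary.  Plan/metric provenance travels as JSON sidecars and
metric tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .phantom import MaterialMap, StructureSet


def write_volume(array: np.ndarray, spacing_mm, origin_mm, path) -> None:
    """Write a 3-D array as NRRD with physical spacing/origin in mm."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...], tuple[float, ...]]:
    """Read an NRRD volume; returns ``(array[x, y, z], spacing_mm, origin_mm)``."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_materials(materials: MaterialMap, path) -> None:
    write_volume(
        materials.labels.astype(np.uint8), materials.spacing_mm, materials.origin_mm, path
    )


def read_materials(path) -> MaterialMap:
    arr, spacing, origin = read_volume(path)
    return MaterialMap(arr.astype(np.int8), spacing, origin)


def write_structures(structures: StructureSet, directory) -> None:
    """One NRRD label volume per mask, named ``<structure>.nrrd``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.masks.items():
        write_volume(
            mask.astype(np.uint8), structures.spacing_mm, structures.origin_mm,
            directory / f"{name}.nrrd",
        )


def read_structures(directory) -> StructureSet:
    directory = Path(directory)
    masks = {}
    spacing = origin = None
    for path in sorted(directory.glob("*.nrrd")):
        arr, spacing, origin = read_volume(path)
        masks[path.stem] = arr.astype(bool)
    if not masks:
        raise FileNotFoundError(f"no structure volumes (*.nrrd) in {directory}")
    return StructureSet(masks=masks, spacing_mm=spacing, origin_mm=origin)


def write_provenance(path, **info) -> None:
    """JSON sidecar describing how a dose map or plan was produced."""

    def coerce(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return str(obj)

    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, default=coerce, sort_keys=True)


def write_dvh_csv(dvh, path) -> None:
    dvh.to_frame().to_csv(path, index=False)
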