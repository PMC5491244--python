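"""Synthetic voxel head phantoms.

The study geometry is a nested-ellipsoid head: a scalp (soft tissue)
shell, a bone (skull) shell, an interior soft-tissue compartment, an
ellipsoidal brain, and a brainstem clinical target volume (CTV) sitting
posterior of the head centre.  Organ-at-risk surrogates are two thin
optic-nerve cylinders running antero-posteriorly and a circle-of-Willis
torus at the skull base.  Anatomical realism is not a goal: the phantom
only has to reproduce the depth-from-surface statistics of a brainstem
target under coplanar axial beams and plausible structure volumes
(normal brain ~1.17 L, optic nerves ~1.6 cm3, circle of Willis ~1 cm3).

Coordinates follow patient LPS: +x left, +y posterior, +z superior.
Grids are indexed ``labels[ix, iy, iz]``; the axial (slice) plane is
x-y.  Spacing is stored in millimetres; geometric parameters are in
centimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np
import yaml


class Material(IntEnum):
    """Voxel material labels (a deliberately small tissue library)."""

    AIR = 0
    SOFT_TISSUE = 1
    BONE = 2
    BRAIN = 3
    TUMOR = 4


#: Mean CT number (HU) assigned to each material by :func:`synthesize_hu`.
HU_MEANS: Mapping[Material, float] = {
    Material.AIR: -1000.0,
    Material.SOFT_TISSUE: 40.0,
    Material.BONE: 700.0,
    Material.BRAIN: 35.0,
    Material.TUMOR: 38.0,
}

#: Default HU thresholds for :func:`assign_materials`.  Bands (low→high)
#: map to air, brain, tumor, soft tissue, bone.  The conventional
#: air/soft and soft/bone splits sit at -500 and +300 HU; the narrow
#: interior bands separate the brain/tumor/soft means (35/38/40 HU) so
#: that a noise-free synthetic CT round-trips exactly.
DEFAULT_HU_THRESHOLDS: tuple[float, ...] = (-500.0, 36.5, 39.0, 300.0)

_THRESHOLD_BANDS: tuple[Material, ...] = (
    Material.AIR,
    Material.BRAIN,
    Material.TUMOR,
    Material.SOFT_TISSUE,
    Material.BONE,
)


class GeometryError(ValueError):
    """Raised when requested phantom geometry is inconsistent."""


@dataclass
class MaterialMap:
    """Labelled voxel grid.

    Attributes
    ----------
    labels : ndarray of int8, shape (nx, ny, nz)
        One :class:`Material` code per voxel.
    spacing_mm : tuple of float
        Voxel pitch per axis, millimetres.
    origin_mm : tuple of float
        Physical position (mm, LPS) of the centre of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing_cm(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float) / 10.0

    @property
    def origin_cm(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float) / 10.0

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_cm))

    def coords_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical voxel-centre coordinates in cm."""
        o, s = self.origin_cm, self.spacing_cm
        return tuple(o[a] + s[a] * np.arange(self.labels.shape[a]) for a in range(3))


@dataclass
class StructureSet:
    """Named binary masks sharing a :class:`MaterialMap` grid."""

    masks: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(np.asarray(self.spacing_mm) / 10.0))

    def volumes_cm3(self) -> dict[str, float]:
        vv = self.voxel_volume_cm3
        return {name: float(mask.sum()) * vv for name, mask in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass
class PhantomParams:
    """Generator parameters (cm unless noted).

    Defaults reproduce the study's geometry statistics: deepest CTV
    depth ~11.8 cm from the anterior surface, ~9.2 cm posterior and
    ~9.5 cm lateral, with normal-brain volume near 1166 cm3.  ``jitter``
    is the fractional standard deviation applied to the head/brain/CTV
    scale per phantom (truncated at 2.5 sigma) so a seeded cohort spans
    a plausible inter-patient range without leaving those bands.
    """

    head_semiaxes_cm: tuple[float, float, float] = (7.8, 8.9, 10.5)
    scalp_thickness_cm: float = 0.5
    skull_thickness_cm: float = 0.7
    brain_semiaxes_cm: tuple[float, float, float] = (6.2, 6.9, 6.3)
    ctv_semiaxes_cm: tuple[float, float, float] = (1.8, 1.6, 2.2)
    ctv_offset_cm: tuple[float, float, float] = (0.0, 1.28, 0.0)
    optic_nerve_radius_cm: float = 0.36
    optic_nerve_y_range_cm: tuple[float, float] = (-5.2, -0.6)
    optic_nerve_x_offset_cm: float = 1.5
    optic_nerve_z_offset_cm: float = 0.0
    willis_major_radius_cm: float = 0.8
    willis_minor_radius_cm: float = 0.25
    willis_center_cm: tuple[float, float, float] = (0.0, -1.0, -2.6)
    hu_noise_sd: float = 20.0
    voxel_size_mm: float = 2.0
    margin_cm: float = 0.6
    jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_semiaxes_cm", "brain_semiaxes_cm", "ctv_semiaxes_cm"):
            if any(a <= 0 for a in getattr(self, name)):
                raise GeometryError(f"{name} must be positive")
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")
        if self.jitter < 0:
            raise GeometryError("jitter must be nonnegative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid (semiaxes in cm)."""
    x, y, z = coords
    q = (
        ((x[:, None, None] - center[0]) / semiaxes[0]) ** 2
        + ((y[None, :, None] - center[1]) / semiaxes[1]) ** 2
        + ((z[None, None, :] - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def _truncated_normal(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """N(0, sd) truncated at +/- 2.5 sigma (keeps jittered anatomy sane)."""
    draw = rng.normal(0.0, sd, size=size)
    if sd == 0:
        return draw
    return np.clip(draw, -2.5 * sd, 2.5 * sd)


def generate_head_phantom(params: PhantomParams) -> tuple[MaterialMap, StructureSet]:
    """Generate a seeded voxel head phantom and its structure set.

    Deterministic given ``params.seed``.  Per-phantom anatomy is the
    default geometry perturbed by truncated-Gaussian scale factors
    (common head scale plus per-axis factors) and a small CTV position
    jitter, emulating inter-patient variation.

    Returns
    -------
    (MaterialMap, StructureSet)
        The structure set holds masks ``body``, ``ctv``, ``nb`` (brain
        minus CTV), ``l_on``, ``r_on`` and ``cw``.

    Raises
    ------
    GeometryError
        If the jittered CTV does not fit inside the brain.
    """
    rng = np.random.default_rng(params.seed)
    j = params.jitter

    common = 1.0 + _truncated_normal(rng, j)
    head = np.asarray(params.head_semiaxes_cm) * common * (
        1.0 + _truncated_normal(rng, j / 2.0, 3)
    )
    brain = np.asarray(params.brain_semiaxes_cm) * common * (
        1.0 + _truncated_normal(rng, j / 2.0, 3)
    )
    ctv_semi = np.asarray(params.ctv_semiaxes_cm) * (
        1.0 + _truncated_normal(rng, j, 3)
    )
    ctv_center = np.asarray(params.ctv_offset_cm) + np.array(
        [_truncated_normal(rng, 0.05), _truncated_normal(rng, 0.10), 0.0]
    )

    h_cm = params.voxel_size_mm / 10.0
    half_extent = head + params.margin_cm
    n = (2 * np.ceil(half_extent / h_cm) + 1).astype(int)
    origin_cm = -((n - 1) / 2.0) * h_cm
    coords = tuple(origin_cm[a] + h_cm * np.arange(n[a]) for a in range(3))

    labels = np.full(tuple(n), int(Material.AIR), dtype=np.int8)
    body = _ellipsoid(coords, (0, 0, 0), head)
    labels[body] = Material.SOFT_TISSUE
    outer_skull = head - params.scalp_thickness_cm
    inner_skull = outer_skull - params.skull_thickness_cm
    if np.any(inner_skull <= 0):
        raise GeometryError("scalp+skull thicker than head semi-axes")
    shell = _ellipsoid(coords, (0, 0, 0), outer_skull) & ~_ellipsoid(
        coords, (0, 0, 0), inner_skull
    )
    labels[shell] = Material.BONE
    brain_mask = _ellipsoid(coords, (0, 0, 0), brain)
    if np.any(brain_mask & ~_ellipsoid(coords, (0, 0, 0), inner_skull)):
        raise GeometryError("brain extends into or beyond the skull shell")
    labels[brain_mask] = Material.BRAIN
    ctv = _ellipsoid(coords, ctv_center, ctv_semi)
    if np.any(ctv & ~brain_mask):
        raise GeometryError("CTV extends outside the brain")
    labels[ctv] = Material.TUMOR

    x, y, z = coords
    xg = x[:, None, None]
    yg = y[None, :, None]
    zg = z[None, None, :]

    def nerve(sign: float) -> np.ndarray:
        x0 = sign * params.optic_nerve_x_offset_cm * common
        z0 = params.optic_nerve_z_offset_cm
        y_lo, y_hi = params.optic_nerve_y_range_cm
        radial = (xg - x0) ** 2 + (zg - z0) ** 2 <= params.optic_nerve_radius_cm**2
        mask = radial & (yg >= y_lo * common) & (yg <= y_hi * common)
        return mask & brain_mask & ~ctv

    l_on = nerve(+1.0)
    r_on = nerve(-1.0)

    wc = np.asarray(params.willis_center_cm) * common
    ring = np.sqrt((xg - wc[0]) ** 2 + (yg - wc[1]) ** 2) - params.willis_major_radius_cm
    cw = (ring**2 + (zg - wc[2]) ** 2 <= params.willis_minor_radius_cm**2)
    cw = cw & brain_mask & ~ctv

    spacing_mm = (params.voxel_size_mm,) * 3
    origin_mm = tuple(10.0 * origin_cm)
    materials = MaterialMap(labels, spacing_mm, origin_mm)
    structures = StructureSet(
        masks={
            "body": labels != Material.AIR,
            "ctv": ctv,
            "nb": brain_mask & ~ctv,
            "l_on": l_on,
            "r_on": r_on,
            "cw": cw,
        },
        spacing_mm=spacing_mm,
        origin_mm=origin_mm,
    )
    return materials, structures


def synthesize_hu(
    materials: MaterialMap, noise_sd: float = 20.0, seed: int = 0
) -> np.ndarray:
    """Synthetic CT: per-material mean HU plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    hu = np.empty(materials.shape, dtype=float)
    for mat, mean in HU_MEANS.items():
        hu[materials.labels == mat] = mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd, size=materials.shape)
    return hu


def assign_materials(
    hu: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_HU_THRESHOLDS,
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> MaterialMap:
    """Threshold a HU grid back into a :class:`MaterialMap`.

    The four default thresholds split HU into air / brain / tumor /
    soft-tissue / bone bands and invert :func:`synthesize_hu` exactly
    at zero noise.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or len(thr) != len(_THRESHOLD_BANDS) - 1:
        raise ValueError(f"expected {len(_THRESHOLD_BANDS) - 1} thresholds")
    if np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    band = np.searchsorted(thr, hu, side="right")
    codes = np.asarray([int(m) for m in _THRESHOLD_BANDS], dtype=np.int8)
    return MaterialMap(codes[band], tuple(spacing_mm), tuple(origin_mm))
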