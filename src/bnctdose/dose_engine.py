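"""Per-field dose computation on voxel phantoms.

A field is a parallel (non-divergent) coplanar beam entering the head
at an axial gantry-style angle: 0 deg anterior, 90 deg left, 180 deg
posterior, 270 deg right, rotating anterior->left in the axial plane.
For every in-body voxel the engine evaluates the four central-axis
component curves at the voxel's radiological depth (water-equivalent
path length from the body entry surface) and scales them by the
collimator's radial profile.  Biological weighting then follows the
standard two steps: per-component DRSF adjustment, and RBE/CBE
weighting with the boron term scaled by local B-10 concentration.

Radiological depth uses water-equivalent factors of 0 for air, 1.0 for
soft tissue / brain / tumor and 1.4 for bone.  Depth maps are computed
by resampling the density grid into a beam-aligned frame, accumulating
a midpoint-rule cumulative path integral along the beam axis, and
resampling back — exact for parallel beams up to linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.ndimage import map_coordinates

from .beam_model import (
    BeamModelParams,
    COMPONENTS,
    RadiobiologyParams,
    component_depth_dose_rate,
    lateral_fluence_factor,
    radial_profile,
)
from .phantom import Material, MaterialMap, StructureSet

if TYPE_CHECKING:  # pragma: no cover
    from .planner import BeamSpec

#: Water-equivalent density used for radiological depth, per material.
WATER_EQUIVALENT_DENSITY = {
    Material.AIR: 0.0,
    Material.SOFT_TISSUE: 1.0,
    Material.BONE: 1.4,
    Material.BRAIN: 1.0,
    Material.TUMOR: 1.0,
}


class DoseGridMismatchError(ValueError):
    """Operands live on different voxel grids."""


class DrsfAlreadyAppliedError(RuntimeError):
    """Guard against applying the DRSF adjustment twice."""


@dataclass
class ComponentDoseMap:
    """Per-voxel physical dose rates (Gy/min) of one field's components.

    The B-10 grid is stored per reference boron concentration; local
    concentration scaling happens in :func:`rbe_weighted_dose`.
    ``drsf_applied`` records whether the maps are raw (D) or adjusted
    (Dadj) components.
    """

    thermal: np.ndarray
    fast: np.ndarray
    photon: np.ndarray
    b10: np.ndarray
    field_id: str = ""
    drsf_applied: bool = False

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise ValueError(f"unknown component {name!r}")
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.thermal.shape


@dataclass
class BoronMap:
    """Voxelwise B-10 concentration (ppm)."""

    concentration_ppm: np.ndarray
    reference_ppm: float


@dataclass
class RbeDoseMap:
    """Biologically weighted dose (Gy-Eq) with delivery provenance."""

    dose_gy_eq: np.ndarray
    provenance: dict = field(default_factory=dict)


def beam_direction(angle_deg: float) -> np.ndarray:
    """Unit propagation vector (LPS) of an axial field at ``angle_deg``."""
    theta = np.deg2rad(angle_deg)
    vec = np.array([-np.sin(theta), np.cos(theta), 0.0])
    # snap axis-aligned angles exactly: 1e-16 residues flip boundary
    # samples to the outside of the grid during resampling
    vec[np.abs(vec) < 1e-12] = 0.0
    return vec


def _density_grid(materials: MaterialMap) -> np.ndarray:
    table = np.zeros(max(int(m) for m in Material) + 1)
    for mat, rho in WATER_EQUIVALENT_DENSITY.items():
        table[int(mat)] = rho
    return table[materials.labels]


def path_depth_map(
    density: np.ndarray,
    spacing_cm: np.ndarray,
    origin_cm: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Per-voxel path integral of ``density`` from upstream grid edge (cm).

    Because air carries zero density, the integral from the grid edge
    equals the water-equivalent depth from the body entry surface for
    any convex phantom surrounded by air.
    """
    nx, ny, nz = density.shape
    hx, hy, hz = spacing_cm
    if not np.isclose(hx, hy):
        raise ValueError("in-plane spacing must be isotropic for axial fields")
    h = float(hx)
    b = beam_direction(angle_deg)[:2]
    nvec = np.array([b[1], -b[0]])  # in-plane normal

    extent = np.array([nx - 1, ny - 1]) * np.array([hx, hy])
    center = origin_cm[:2] + extent / 2.0
    half_diag = 0.5 * float(np.hypot(*extent)) + h
    # symmetric sample grid so opposed beams resample mirror-identically
    n_half = int(np.ceil(half_diag / h))
    uv = (np.arange(2 * n_half + 1) - n_half) * h
    half_diag = n_half * h

    u = uv[:, None]
    v = uv[None, :]
    px = center[0] + u * b[0] + v * nvec[0]
    py = center[1] + u * b[1] + v * nvec[1]
    ix = (px - origin_cm[0]) / hx
    iy = (py - origin_cm[1]) / hy
    nu = uv.size
    coords = np.empty((3, nu, nu, nz))
    coords[0] = ix[..., None]
    coords[1] = iy[..., None]
    coords[2] = np.arange(nz)[None, None, :]
    rho_rot = map_coordinates(density.astype(float), coords, order=1, cval=0.0)

    # midpoint rule: depth at a sample's centre counts half of its own cell
    depth_rot = h * (np.cumsum(rho_rot, axis=0) - 0.5 * rho_rot)

    x = origin_cm[0] + hx * np.arange(nx)
    y = origin_cm[1] + hy * np.arange(ny)
    dx = x[:, None] - center[0]
    dy = y[None, :] - center[1]
    uu = dx * b[0] + dy * b[1]
    vv = dx * nvec[0] + dy * nvec[1]
    iu = (uu + half_diag) / h
    iv = (vv + half_diag) / h
    back = np.empty((3, nx, ny, nz))
    back[0] = iu[..., None]
    back[1] = iv[..., None]
    back[2] = np.arange(nz)[None, None, :]
    return map_coordinates(depth_rot, back, order=1, cval=0.0)


def radiological_depth_map(materials: MaterialMap, angle_deg: float) -> np.ndarray:
    """Water-equivalent depth (cm) of every voxel for one field angle."""
    return path_depth_map(
        _density_grid(materials), materials.spacing_cm, materials.origin_cm, angle_deg
    )


def geometric_depth_map(
    body_mask: np.ndarray,
    spacing_cm: np.ndarray,
    origin_cm: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Geometric distance (cm) from the body entry surface along the beam."""
    return path_depth_map(
        body_mask.astype(float), np.asarray(spacing_cm), np.asarray(origin_cm), angle_deg
    )


def radiological_depth(
    materials: MaterialMap, beam: "BeamSpec", voxel: tuple[int, int, int],
    step_cm: float = 0.01,
) -> float:
    """Radiological depth of a single voxel by direct ray marching.

    Marches upstream from the voxel centre in ``step_cm`` increments,
    sampling the water-equivalent density with trilinear interpolation.
    Convenience/reference path for the vectorised depth maps.
    """
    density = _density_grid(materials).astype(float)
    spacing = materials.spacing_cm
    origin = materials.origin_cm
    b = beam_direction(beam.angle_deg)
    p0 = origin + spacing * np.asarray(voxel, dtype=float)
    extent = spacing * (np.asarray(density.shape) - 1)
    max_len = float(np.linalg.norm(extent)) + 1.0
    n_steps = int(np.ceil(max_len / step_cm))
    # sample at segment midpoints walking back toward the source
    s = (np.arange(n_steps) + 0.5) * step_cm
    pts = p0[None, :] - s[:, None] * b[None, :]
    idx = (pts - origin[None, :]) / spacing[None, :]
    rho = map_coordinates(density, idx.T, order=1, cval=0.0)
    return float(rho.sum() * step_cm)


def trace_field(
    materials: MaterialMap,
    structures: StructureSet,
    beam: "BeamSpec",
    bm: BeamModelParams,
    isocenter_cm: np.ndarray | None = None,
    depth_map: np.ndarray | None = None,
) -> ComponentDoseMap:
    """Compute one field's four-component dose-rate maps (weight 1).

    ``isocenter_cm`` (default: CTV centroid) fixes the beam axis; the
    relative field weight is applied later at plan level.  A precomputed
    radiological ``depth_map`` may be passed to share work across
    fields.  If the field misses the body entirely an all-zero map is
    returned with a warning.
    """
    spacing = materials.spacing_cm
    origin = materials.origin_cm
    if depth_map is None:
        depth_map = radiological_depth_map(materials, beam.angle_deg)
    if isocenter_cm is None:
        ctv = structures["ctv"]
        if not ctv.any():
            raise ValueError("empty CTV: cannot place isocenter")
        isocenter_cm = origin + spacing * np.array(
            [idx.mean() for idx in np.nonzero(ctv)]
        )

    b = beam_direction(beam.angle_deg)
    x, y, z = (origin[a] + spacing[a] * np.arange(materials.shape[a]) for a in range(3))
    dx = x[:, None, None] - isocenter_cm[0]
    dy = y[None, :, None] - isocenter_cm[1]
    dz = z[None, None, :] - isocenter_cm[2]
    along = dx * b[0] + dy * b[1] + dz * b[2]
    r2 = dx**2 + dy**2 + dz**2 - along**2
    r = np.sqrt(np.maximum(r2, 0.0))

    bm_field = replace(bm, collimator_diameter_cm=beam.collimator_diameter_cm)
    profile = radial_profile(r, bm_field)
    body = structures["body"]
    # neutron-driven components carry the in-phantom transverse leakage
    # falloff; the penetrating photon component keeps only the
    # collimator profile
    neutron_shaping = profile * lateral_fluence_factor(r, bm_field) * body
    photon_shaping = profile * body

    comps = {}
    for name in COMPONENTS:
        shaping = photon_shaping if name == "photon" else neutron_shaping
        comps[name] = component_depth_dose_rate(depth_map, name, bm) * shaping
    out = ComponentDoseMap(
        thermal=comps["thermal"],
        fast=comps["fast"],
        photon=comps["photon"],
        b10=comps["b10"],
        field_id=f"{beam.angle_deg:g}deg",
    )
    if not np.any(out.thermal + out.fast + out.photon + out.b10 > 0):
        warnings.warn(
            f"field at {beam.angle_deg:g} deg misses the body: all-zero dose map",
            stacklevel=2,
        )
    return out


def apply_drsf(raw: ComponentDoseMap, rb: RadiobiologyParams) -> ComponentDoseMap:
    """Per-component DRSF adjustment D -> Dadj.

    Refuses maps whose provenance flag shows the adjustment was already
    applied.
    """
    if raw.drsf_applied:
        raise DrsfAlreadyAppliedError("DRSF adjustment already applied to this map")
    return ComponentDoseMap(
        thermal=rb.drsf_thermal * raw.thermal,
        fast=rb.drsf_fast * raw.fast,
        photon=rb.drsf_photon * raw.photon,
        b10=rb.drsf_b10 * raw.b10,
        field_id=raw.field_id,
        drsf_applied=True,
    )


def build_boron_map(
    structures: StructureSet, rb: RadiobiologyParams, ref_conc_ppm: float = 25.0
) -> BoronMap:
    """Two-compartment boron distribution: T/N x reference inside the CTV,
    reference elsewhere in the body, zero in air."""
    if ref_conc_ppm <= 0:
        raise ValueError("reference concentration must be positive")
    conc = np.where(structures["body"], ref_conc_ppm, 0.0)
    conc = np.where(structures["ctv"], rb.tn_ratio * ref_conc_ppm, conc)
    return BoronMap(concentration_ppm=conc, reference_ppm=ref_conc_ppm)


def rbe_weighted_dose(
    adj: ComponentDoseMap,
    boron: BoronMap,
    structures: StructureSet,
    rb: RadiobiologyParams,
    beam_minutes: float = 1.0,
) -> RbeDoseMap:
    """Total biologically weighted dose (Gy-Eq) from adjusted components.

    Per voxel::

        minutes * ( RBE_th*Dadj_th + RBE_fast*Dadj_fast
                    + RBE_ph*Dadj_ph
                    + CBE(tissue) * (c_B / c_ref) * Dadj_B10 )

    with CBE(tumor) inside the CTV mask and CBE(brain) elsewhere.  The
    CTV mask — not the material label — selects the tumor CBE, since
    target voxels are tumor radiobiologically even where their density
    is brain-like.
    """
    shape = adj.shape
    if boron.concentration_ppm.shape != shape or structures["ctv"].shape != shape:
        raise DoseGridMismatchError("component, boron and structure grids differ")
    cbe = np.where(structures["ctv"], rb.cbe_tumor, rb.cbe_brain)
    boron_scale = boron.concentration_ppm / boron.reference_ppm
    rate = (
        rb.rbe_thermal * adj.thermal
        + rb.rbe_fast * adj.fast
        + rb.rbe_photon * adj.photon
        + cbe * boron_scale * adj.b10
    )
    return RbeDoseMap(
        dose_gy_eq=beam_minutes * rate,
        provenance={
            "field_id": adj.field_id,
            "beam_minutes": beam_minutes,
            "drsf_applied": adj.drsf_applied,
        },
    )


def field_rbe_rate_map(
    materials: MaterialMap,
    structures: StructureSet,
    beam: "BeamSpec",
    bm: BeamModelParams,
    rb: RadiobiologyParams,
    boron: BoronMap | None = None,
    depth_map: np.ndarray | None = None,
    isocenter_cm: np.ndarray | None = None,
) -> np.ndarray:
    """Convenience: one field's RBE-weighted dose rate (Gy-Eq/min, weight 1)."""
    if boron is None:
        boron = build_boron_map(structures, rb, bm.reference_boron_ppm)
    raw = trace_field(
        materials, structures, beam, bm, isocenter_cm=isocenter_cm, depth_map=depth_map
    )
    adj = apply_drsf(raw, rb)
    return rbe_weighted_dose(adj, boron, structures, rb, beam_minutes=1.0).dose_gy_eq
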