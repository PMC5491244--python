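"""DVH computation and plan-quality metrics.

Implements the dosimetric endpoints of the study: cumulative
dose-volume histograms, Dx/Vx lookups by linear interpolation,
homogeneity index D5/D95, integral dose (mean dose x volume, Gy-Eq.L),
therapeutic gain CTVmin/NTmax, organ-at-risk tolerance checks and
deepest-tumor-depth measurement per beam angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dose_engine
from .phantom import StructureSet

#: Maximal-dose tolerances (Gy-Eq) for the organs at risk: normal brain
#: < 13, optic nerves < 10, circle of Willis < 12.  Comparisons are
#: strict (a dose exactly at the limit fails), matching the "< limit"
#: notation of the tolerance references.
DEFAULT_TOLERANCES_GY_EQ = {"nb": 13.0, "l_on": 10.0, "r_on": 10.0, "cw": 12.0}


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``volume_fraction[k]`` is the fraction of the structure receiving at
    least ``edges_gy_eq[k]``; it starts at 1, is non-increasing and ends
    at 0.
    """

    edges_gy_eq: np.ndarray
    volume_fraction: np.ndarray
    structure: str = ""
    volume_cm3: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy_eq": self.edges_gy_eq, "volume_fraction": self.volume_fraction}
        )


def cumulative_dvh(
    dose: np.ndarray,
    mask: np.ndarray,
    voxel_volume_cm3: float,
    bin_width: float = 0.05,
    structure: str = "",
) -> DVH:
    """Exact voxel-counting cumulative DVH with edges every ``bin_width``."""
    if not mask.any():
        raise ValueError(f"empty mask for structure {structure!r}")
    doses = np.asarray(dose[mask], dtype=float)
    top = float(doses.max())
    edges = np.arange(0.0, top + 2.0 * bin_width, bin_width)
    # exact survival fraction at every edge
    order = np.sort(doses)
    below = np.searchsorted(order, edges, side="left")
    frac = 1.0 - below / doses.size
    return DVH(
        edges_gy_eq=edges,
        volume_fraction=frac,
        structure=structure,
        volume_cm3=doses.size * voxel_volume_cm3,
    )


def dose_at_volume(dvh: DVH, v: float) -> float:
    """Dose received by at least fraction ``v`` of the structure.

    Linear interpolation of the inverse cumulative curve; D95 is
    ``dose_at_volume(dvh, 0.95)``, D5 ``dose_at_volume(dvh, 0.05)``.
    """
    if not 0.0 < v <= 1.0:
        raise ValueError("volume fraction must lie in (0, 1]")
    frac = dvh.volume_fraction
    edges = dvh.edges_gy_eq
    below = np.nonzero(frac < v)[0]
    if below.size == 0:  # whole curve >= v (can't happen: curve ends at 0)
        return float(edges[-1])
    i = int(below[0])
    if i == 0:
        return float(edges[0])
    f1, f2 = frac[i - 1], frac[i]
    d1, d2 = edges[i - 1], edges[i]
    return float(d1 + (f1 - v) / (f1 - f2) * (d2 - d1))


def homogeneity_index(dvh: DVH) -> float:
    """HI = D5 / D95 inside the target; 1 means perfectly uniform."""
    d95 = dose_at_volume(dvh, 0.95)
    d5 = dose_at_volume(dvh, 0.05)
    if d95 <= 0:
        raise ValueError("D95 is zero: homogeneity index undefined")
    return d5 / d95


def integral_dose(dose: np.ndarray, mask: np.ndarray, voxel_volume_cm3: float) -> float:
    """Integral dose = mean dose x structure volume, in Gy-Eq.L."""
    if not mask.any():
        raise ValueError("empty mask")
    vals = dose[mask]
    volume_l = vals.size * voxel_volume_cm3 / 1000.0
    return float(vals.mean()) * volume_l


def therapeutic_gain(ctv_min: float, nt_max: float) -> float:
    """CTVmin / NTmax; above 1 every target voxel beats every NT voxel."""
    if nt_max <= 0:
        raise ValueError("NTmax must be positive")
    return ctv_min / nt_max


def structure_metrics(
    dose: np.ndarray,
    mask: np.ndarray,
    voxel_volume_cm3: float,
    bin_width: float = 0.05,
    structure: str = "",
) -> dict[str, float]:
    """Dmin/Dmax/Dmean, DVH-interpolated D95/D5 and integral dose.

    D95/D5 come from the cumulative curve and are clamped into
    [Dmin, Dmax] so the ordering chain Dmin <= D95 <= Dmean <= D5 <=
    Dmax survives the half-bin interpolation error of degenerate
    (near-uniform) dose distributions.
    """
    vals = np.asarray(dose[mask], dtype=float)
    dvh = cumulative_dvh(dose, mask, voxel_volume_cm3, bin_width, structure)
    dmin, dmax = float(vals.min()), float(vals.max())
    d95 = min(max(dose_at_volume(dvh, 0.95), dmin), dmax)
    d5 = min(max(dose_at_volume(dvh, 0.05), dmin), dmax)
    return {
        "volume_cm3": dvh.volume_cm3,
        "d_min": dmin,
        "d_max": dmax,
        "d_mean": float(vals.mean()),
        "d95": d95,
        "d5": d5,
        "integral_dose_gy_eq_l": integral_dose(dose, mask, voxel_volume_cm3),
    }


def oar_metrics(
    dose: np.ndarray,
    structures: StructureSet,
    tolerances_gy_eq: dict[str, float] | None = None,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-OAR Dmean/Dmax/ID and strict maximal-dose tolerance flags.

    Structures named in the tolerance table but absent from the
    structure set are reported with ``present = False`` rather than
    silently skipped.
    """
    tolerances = dict(DEFAULT_TOLERANCES_GY_EQ if tolerances_gy_eq is None else tolerances_gy_eq)
    rows = []
    vv = structures.voxel_volume_cm3
    for name, limit in tolerances.items():
        if name not in structures or not structures[name].any():
            rows.append(
                {"structure": name, "present": False, "tolerance_gy_eq": limit}
            )
            continue
        m = structure_metrics(dose, structures[name], vv, bin_width, name)
        rows.append(
            {
                "structure": name,
                "present": True,
                "volume_cm3": m["volume_cm3"],
                "d_mean": m["d_mean"],
                "d_max": m["d_max"],
                "integral_dose_gy_eq_l": m["integral_dose_gy_eq_l"],
                "tolerance_gy_eq": limit,
                "within_tolerance": m["d_max"] < limit,
            }
        )
    return pd.DataFrame(rows)


def max_tumor_depth(
    body_mask: np.ndarray,
    ctv_mask: np.ndarray,
    angle_deg: float,
    spacing_cm,
    origin_cm,
) -> float:
    """Deepest CTV voxel depth (cm) from the body surface at one angle.

    Geometric — not radiological — distance along the beam direction,
    matching depth measured on CT images.
    """
    if not body_mask.any() or not ctv_mask.any():
        raise ValueError("body and CTV masks must be nonempty")
    depth = dose_engine.geometric_depth_map(
        body_mask, np.asarray(spacing_cm, float), np.asarray(origin_cm, float), angle_deg
    )
    return float(depth[ctv_mask].max())


def plan_metrics(
    dose: np.ndarray,
    structures: StructureSet,
    bin_width: float = 0.05,
    tolerances_gy_eq: dict[str, float] | None = None,
) -> dict:
    """Full metric bundle for one normalized plan dose map.

    Returns a flat dict with CTV dose statistics and homogeneity index,
    therapeutic gain against NT = body minus CTV, and per-OAR metrics
    prefixed by structure name.
    """
    vv = structures.voxel_volume_cm3
    ctv = structures["ctv"]
    nt_mask = structures["body"] & ~ctv
    ctv_m = structure_metrics(dose, ctv, vv, bin_width, "ctv")
    nt_max = float(dose[nt_mask].max())
    out = {
        "ctv_volume_cm3": ctv_m["volume_cm3"],
        "ctv_min": ctv_m["d_min"],
        "ctv_max": ctv_m["d_max"],
        "ctv_mean": ctv_m["d_mean"],
        "ctv_d95": ctv_m["d95"],
        "ctv_d5": ctv_m["d5"],
        "hi": ctv_m["d5"] / ctv_m["d95"],
        "nt_max": nt_max,
        "gain": therapeutic_gain(ctv_m["d_min"], nt_max),
    }
    oar = oar_metrics(dose, structures, tolerances_gy_eq, bin_width)
    for _, row in oar.iterrows():
        name = row["structure"]
        if not row["present"]:
            out[f"{name}_present"] = False
            continue
        out[f"{name}_present"] = True
        out[f"{name}_volume_cm3"] = row["volume_cm3"]
        out[f"{name}_dmean"] = row["d_mean"]
        out[f"{name}_dmax"] = row["d_max"]
        out[f"{name}_id_gy_eq_l"] = row["integral_dose_gy_eq_l"]
        out[f"{name}_within_tolerance"] = bool(row["within_tolerance"])
    return out
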