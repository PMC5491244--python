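"""Multi-field plan assembly.

A plan is a set of coplanar axial fields (standard 1F/2F/3F/4F angle
sets), relative field weights balanced so each field's maximal
normal-tissue dose contribution agrees within a tolerance (the study's
10% rule, automated as a fixed-point iteration), and a global scale
fixing total beam-on time so the prescription — 20 Gy-Eq covering 80%
of the CTV — is met exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard coplanar angle sets, degrees (0 anterior, 90 left, 180
#: posterior, 270 right).  The single field exists only to demonstrate
#: that one port cannot treat a target deeper than the advantage depth.
STANDARD_ANGLES = {
    1: (0.0,),
    2: (90.0, 270.0),
    3: (60.0, 180.0, 300.0),
    4: (0.0, 90.0, 180.0, 270.0),
}


class BalanceError(RuntimeError):
    """Weight balancing failed to converge (should not happen for
    positive dose maps; guarded anyway)."""


@dataclass
class BeamSpec:
    """One coplanar field: axial angle, collimator, relative weight."""

    angle_deg: float
    collimator_diameter_cm: float = 14.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg < 360.0:
            raise ValueError("angle must lie in [0, 360)")
        if self.weight <= 0:
            raise ValueError("field weight must be positive")
        if self.collimator_diameter_cm <= 0:
            raise ValueError("collimator diameter must be positive")


@dataclass
class Plan:
    """An assembled, normalized multi-field plan."""

    fields: list[BeamSpec]
    field_minutes: np.ndarray
    total_minutes: float
    rx_dose_gy_eq: float
    coverage: float
    normalization_scale: float = 1.0
    meta: dict = field(default_factory=dict)


def standard_field_set(n: int, collimator_diameter_cm: float = 14.0) -> list[BeamSpec]:
    """The study's standard 1F/2F/3F/4F field arrangements, weight 1 each."""
    if n not in STANDARD_ANGLES:
        raise ValueError(f"no standard field set for n={n}; choose 1-4")
    return [
        BeamSpec(angle_deg=a, collimator_diameter_cm=collimator_diameter_cm)
        for a in STANDARD_ANGLES[n]
    ]


def balance_field_weights(
    per_field_rbe_maps: list[np.ndarray],
    nt_mask: np.ndarray,
    tolerance: float = 0.10,
    max_iter: int = 100,
) -> np.ndarray:
    """Balance relative weights so per-field NT-max contributions agree.

    Each field's figure is the maximum of its own weighted dose-rate map
    over the normal-tissue mask (body minus CTV by convention).  The
    update ``w_i <- w_i / NTmax_i(w)`` equalises them in one step for
    fixed maps; iteration continues until the relative spread
    ``(max - min) / max`` is within ``tolerance``.  Weights are returned
    normalized to mean 1.
    """
    if len(per_field_rbe_maps) < 2:
        raise ValueError("balancing needs at least two fields")
    if not nt_mask.any():
        raise ValueError("empty normal-tissue mask")
    nt_max = np.array([float(m[nt_mask].max()) for m in per_field_rbe_maps])
    if np.any(nt_max <= 0):
        raise ValueError("every field must deposit dose in normal tissue")

    w = np.ones(len(per_field_rbe_maps))
    for _ in range(max_iter):
        per_field = w * nt_max
        spread = (per_field.max() - per_field.min()) / per_field.max()
        if spread <= tolerance:
            return w / w.mean()
        w = w / nt_max
    raise BalanceError(f"no convergence within {max_iter} iterations")


def dose_exceeded_by_fraction(doses: np.ndarray, coverage: float) -> float:
    """Dose level exceeded by exactly ``coverage`` of the voxels.

    The exact (linearly interpolated) empirical quantile; the continuum
    limit of inverting a cumulative DVH.  ``coverage`` 1.0 returns the
    minimum dose.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    return float(np.quantile(np.asarray(doses, dtype=float), 1.0 - coverage))


def normalize_to_prescription(
    summed_rbe_per_minute: np.ndarray,
    ctv_mask: np.ndarray,
    rx_dose_gy_eq: float = 20.0,
    coverage: float = 0.8,
) -> tuple[float, np.ndarray]:
    """Scale beam-on time so the CTV coverage dose equals the prescription.

    Returns ``(total_minutes, dose_map)`` with ``dose_map`` in Gy-Eq.
    """
    if not ctv_mask.any():
        raise ValueError("empty CTV mask")
    ctv_rates = summed_rbe_per_minute[ctv_mask]
    d_cov = dose_exceeded_by_fraction(ctv_rates, coverage)
    if d_cov <= 0:
        raise ValueError("zero dose rate at the coverage level inside the CTV")
    total_minutes = rx_dose_gy_eq / d_cov
    return total_minutes, total_minutes * summed_rbe_per_minute


def beam_on_times(weights: np.ndarray, total_minutes: float) -> np.ndarray:
    """Split total beam-on time across sequentially delivered fields,
    proportionally to field weight."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return total_minutes * w / w.sum()


def assemble_plan(
    per_field_rbe_maps: list[np.ndarray],
    field_specs: list[BeamSpec],
    ctv_mask: np.ndarray,
    nt_mask: np.ndarray,
    rx_dose_gy_eq: float = 20.0,
    coverage: float = 0.8,
    tolerance: float = 0.10,
) -> tuple[Plan, np.ndarray]:
    """Balance, combine and normalize one plan.

    Single-field plans skip balancing.  Returns the :class:`Plan` and
    the normalized total RBE dose map (Gy-Eq).
    """
    if len(per_field_rbe_maps) != len(field_specs):
        raise ValueError("one dose map per field spec required")
    n = len(per_field_rbe_maps)
    if n >= 2:
        weights = balance_field_weights(per_field_rbe_maps, nt_mask, tolerance)
    else:
        weights = np.ones(1)
    frac = weights / weights.sum()
    combined_rate = np.zeros_like(per_field_rbe_maps[0])
    for f, m in zip(frac, per_field_rbe_maps):
        combined_rate += f * m
    total_minutes, dose = normalize_to_prescription(
        combined_rate, ctv_mask, rx_dose_gy_eq, coverage
    )
    minutes = beam_on_times(weights, total_minutes)
    specs = [
        BeamSpec(s.angle_deg, s.collimator_diameter_cm, float(w))
        for s, w in zip(field_specs, weights)
    ]
    plan = Plan(
        fields=specs,
        field_minutes=minutes,
        total_minutes=float(total_minutes),
        rx_dose_gy_eq=rx_dose_gy_eq,
        coverage=coverage,
        normalization_scale=float(total_minutes),
        meta={"tolerance": tolerance, "n_fields": n},
    )
    return plan, dose
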