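"""Seeded cohort driver and statistics.

Reruns the study design on synthetic anatomy: N seeded phantoms, each
planned with 2-, 3- and 4-field arrangements, evaluated with the full
metric bundle, then summarised as mean +/- SD per plan type with
one-way ANOVA (and Tukey HSD pairwise comparisons) across plan types.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_engine, evaluate, planner
from .beam_model import BeamModelParams, RadiobiologyParams, load_default_beam
from .phantom import PhantomParams, generate_head_phantom

PLAN_FIELD_COUNTS = {"1F": 1, "2F": 2, "3F": 3, "4F": 4}

#: Metrics summarised in the study tables.
SUMMARY_METRICS = (
    "ctv_min",
    "ctv_max",
    "ctv_mean",
    "ctv_d95",
    "hi",
    "gain",
    "nt_max",
    "total_minutes",
    "nb_dmean",
    "nb_dmax",
    "nb_id_gy_eq_l",
    "l_on_dmean",
    "l_on_dmax",
    "r_on_dmean",
    "r_on_dmax",
    "cw_dmean",
    "cw_dmax",
)


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey-style pairwise p values."""

    f_statistic: float
    p_value: float
    group_means: list[float]
    pairwise_p: dict[tuple[int, int], float]


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Standard between/within mean-square F test across groups.

    Pairwise comparisons use Tukey's honestly-significant-difference
    procedure (studentized range on the pooled within-group variance).
    Identical groups yield F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if msw == 0.0:
        f_stat = 0.0 if ssb == 0.0 else float("inf")
    else:
        f_stat = (ssb / df_b) / msw
    p = 1.0 if f_stat == 0.0 else float(stats.f.sf(f_stat, df_b, df_w))

    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            se = np.sqrt(msw / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            if se == 0.0:
                pairwise[(i, j)] = 1.0 if gi.mean() == gj.mean() else 0.0
                continue
            q = abs(gi.mean() - gj.mean()) / se
            pairwise[(i, j)] = float(stats.studentized_range.sf(q, k, df_w))
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=p,
        group_means=[float(g.mean()) for g in groups],
        pairwise_p=pairwise,
    )


def evaluate_plan_on_phantom(
    materials,
    structures,
    n_fields: int,
    bm: BeamModelParams,
    rb: RadiobiologyParams,
    rx_dose_gy_eq: float = 20.0,
    coverage: float = 0.8,
    tolerance: float = 0.10,
    bin_width: float = 0.05,
    rate_maps_by_angle: dict[float, np.ndarray] | None = None,
):
    """Plan + evaluate one field arrangement on one phantom.

    ``rate_maps_by_angle`` lets callers share per-angle RBE rate maps
    across plan types (superposition makes per-field maps reusable).
    Returns ``(plan, dose_map, metrics dict)``.
    """
    specs = planner.standard_field_set(n_fields)
    boron = dose_engine.build_boron_map(structures, rb, bm.reference_boron_ppm)
    maps = []
    for spec in specs:
        if rate_maps_by_angle is not None and spec.angle_deg in rate_maps_by_angle:
            maps.append(rate_maps_by_angle[spec.angle_deg])
        else:
            m = dose_engine.field_rbe_rate_map(
                materials, structures, spec, bm, rb, boron=boron
            )
            if rate_maps_by_angle is not None:
                rate_maps_by_angle[spec.angle_deg] = m
            maps.append(m)
    ctv = structures["ctv"]
    nt_mask = structures["body"] & ~ctv
    if n_fields >= 2:
        plan, dose = planner.assemble_plan(
            maps, specs, ctv, nt_mask, rx_dose_gy_eq, coverage, tolerance
        )
    else:
        total, dose = planner.normalize_to_prescription(
            maps[0], ctv, rx_dose_gy_eq, coverage
        )
        plan = planner.Plan(
            fields=specs,
            field_minutes=np.array([total]),
            total_minutes=float(total),
            rx_dose_gy_eq=rx_dose_gy_eq,
            coverage=coverage,
            normalization_scale=float(total),
            meta={"n_fields": 1},
        )
    metrics = evaluate.plan_metrics(dose, structures, bin_width)
    metrics["total_minutes"] = plan.total_minutes
    return plan, dose, metrics


def run_cohort(
    n_phantoms: int = 12,
    base_seed: int = 42,
    plan_types: tuple[str, ...] = ("2F", "3F", "4F"),
    phantom_params: PhantomParams | None = None,
    bm: BeamModelParams | None = None,
    rb: RadiobiologyParams | None = None,
    rx_dose_gy_eq: float = 20.0,
    coverage: float = 0.8,
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Full pipeline over a seeded phantom cohort.

    Deterministic given ``base_seed``: phantom ``i`` is generated with
    seed ``base_seed + i``.  Returns one row per (phantom, plan type)
    with every scalar from :func:`evaluate.plan_metrics` plus beam-on
    time; any stage failure aborts with the phantom and stage named.
    """
    if n_phantoms < 2:
        raise ValueError("a cohort needs at least two phantoms")
    unknown = set(plan_types) - set(PLAN_FIELD_COUNTS)
    if unknown:
        raise ValueError(f"unknown plan types: {sorted(unknown)}")
    if bm is None or rb is None:
        default_bm, default_rb = load_default_beam()
        bm = bm if bm is not None else default_bm
        rb = rb if rb is not None else default_rb
    base_params = phantom_params if phantom_params is not None else PhantomParams()

    rows = []
    for i in range(n_phantoms):
        seed = int(base_seed) + i
        params = dataclasses.replace(base_params, seed=seed)
        try:
            materials, structures = generate_head_phantom(params)
        except Exception as exc:  # pragma: no cover - diagnostic wrapper
            raise RuntimeError(f"phantom {i} (seed {seed}): generation failed") from exc
        rate_maps: dict[float, np.ndarray] = {}
        for plan_type in plan_types:
            try:
                _, _, metrics = evaluate_plan_on_phantom(
                    materials,
                    structures,
                    PLAN_FIELD_COUNTS[plan_type],
                    bm,
                    rb,
                    rx_dose_gy_eq,
                    coverage,
                    tolerance,
                    rate_maps_by_angle=rate_maps,
                )
            except Exception as exc:  # pragma: no cover - diagnostic wrapper
                raise RuntimeError(
                    f"phantom {i} (seed {seed}): {plan_type} planning failed"
                ) from exc
            rows.append({"phantom_id": i, "seed": seed, "plan": plan_type, **metrics})
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, metrics: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Mean +/- sample SD per (plan type, metric) with ANOVA p values.

    SD uses n-1 degrees of freedom and is left missing for single-value
    groups; the ANOVA column is filled only when every plan type has at
    least two phantoms.
    """
    if metrics is None:
        metrics = tuple(m for m in SUMMARY_METRICS if m in table.columns)
    plans = sorted(table["plan"].unique(), key=lambda p: PLAN_FIELD_COUNTS.get(p, 99))
    rows = []
    for metric in metrics:
        groups = [table.loc[table["plan"] == p, metric].to_numpy(float) for p in plans]
        if len(groups) >= 2 and all(g.size >= 2 for g in groups):
            p_anova = one_way_anova(groups).p_value
        else:
            p_anova = float("nan")
        for plan, g in zip(plans, groups):
            rows.append(
                {
                    "metric": metric,
                    "plan": plan,
                    "mean": float(g.mean()) if g.size else float("nan"),
                    "sd": float(g.std(ddof=1)) if g.size > 1 else float("nan"),
                    "n": int(g.size),
                    "anova_p": p_anova,
                }
            )
    return pd.DataFrame(rows)
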