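import dataclasses

import numpy as np
import pytest

from bnctdose import study
from bnctdose.beam_model import load_default_beam
from bnctdose.phantom import Material, MaterialMap, PhantomParams, StructureSet, generate_head_phantom

#: Published per-angle deepest-tumor-depth ranges (cm) the default
#: phantom population must stay inside.
TABLE1_DEPTH_RANGES = {
    0.0: (10.79, 12.78),
    60.0: (8.53, 10.85),
    90.0: (8.30, 10.31),
    180.0: (8.52, 10.18),
    270.0: (8.56, 10.76),
    300.0: (9.11, 11.00),
}


@pytest.fixture(scope="session")
def beam_defaults():
    return load_default_beam()


@pytest.fixture(scope="session")
def phantom_seed1():
    return generate_head_phantom(dataclasses.replace(PhantomParams(), seed=1))


@pytest.fixture(scope="session")
def cohort_phantoms():
    """Twelve default phantoms, seeds 1..12."""
    return [
        generate_head_phantom(dataclasses.replace(PhantomParams(), seed=seed))
        for seed in range(1, 13)
    ]


@pytest.fixture(scope="session")
def cohort_table():
    """Full 12-phantom x {2F,3F,4F} cohort run with shipped defaults."""
    return study.run_cohort(n_phantoms=12, base_seed=1)


@pytest.fixture(scope="session")
def seed1_plans(beam_defaults, phantom_seed1):
    """1F-4F plans on the seed-1 phantom, sharing per-angle rate maps.

    Returns ``(plans, rate_maps)`` where plans maps '1F'..'4F' to
    ``(plan, dose, metrics)`` and rate_maps holds the per-angle
    RBE-weighted rate maps (Gy-Eq/min at weight 1).
    """
    bm, rb = beam_defaults
    materials, structures = phantom_seed1
    rate_maps = {}
    plans = {}
    for n_fields in (1, 2, 3, 4):
        plans[f"{n_fields}F"] = study.evaluate_plan_on_phantom(
            materials, structures, n_fields, bm, rb, rate_maps_by_angle=rate_maps
        )
    return plans, rate_maps


def make_water_box(shape=(41, 121, 15), spacing_mm=2.0, ctv="none"):
    """Homogeneous soft-tissue box with an all-body structure set.

    ``ctv`` selects the CTV mask: 'none' (empty), 'all' (every voxel),
    or 'block' (small central block).  Used for slab-geometry engine
    tests where the beam enters the y=0 face at 0 degrees.
    """
    labels = np.full(shape, int(Material.SOFT_TISSUE), dtype=np.int8)
    spacing = (spacing_mm,) * 3
    origin = (0.0, 0.0, 0.0)
    materials = MaterialMap(labels, spacing, origin)
    body = np.ones(shape, dtype=bool)
    if ctv == "all":
        ctv_mask = body.copy()
    elif ctv == "block":
        ctv_mask = np.zeros(shape, dtype=bool)
        cx, cy, cz = (s // 2 for s in shape)
        ctv_mask[cx - 3 : cx + 4, cy - 3 : cy + 4, cz - 2 : cz + 3] = True
    else:
        ctv_mask = np.zeros(shape, dtype=bool)
    structures = StructureSet(
        masks={"body": body, "ctv": ctv_mask, "nb": body & ~ctv_mask},
        spacing_mm=spacing,
        origin_mm=origin,
    )
    return materials, structures
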