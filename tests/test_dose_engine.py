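"""Ray tracing, DRSF adjustment, boron scaling and RBE weighting."""

import numpy as np
import pytest

from bnctdose import dose_engine
from bnctdose.beam_model import (
    BeamModelParams,
    RadiobiologyParams,
    component_depth_dose_rate,
    compute_advantage_depth,
)
from bnctdose.dose_engine import (
    BoronMap,
    ComponentDoseMap,
    DoseGridMismatchError,
    DrsfAlreadyAppliedError,
    apply_drsf,
    build_boron_map,
    radiological_depth,
    rbe_weighted_dose,
    trace_field,
)
from bnctdose.phantom import Material, MaterialMap, StructureSet
from bnctdose.planner import BeamSpec

from conftest import make_water_box


def _unit_components(shape, **kwargs):
    ones = np.ones(shape)
    return ComponentDoseMap(
        thermal=ones.copy(), fast=ones.copy(), photon=ones.copy(), b10=ones.copy(),
        **kwargs,
    )


def _two_voxel_structures():
    """Grid of two voxels: index 0 is tumor (CTV), index 1 normal brain."""
    ctv = np.array([[[True]], [[False]]])
    body = np.ones_like(ctv)
    return StructureSet(
        masks={"body": body, "ctv": ctv, "nb": body & ~ctv},
        spacing_mm=(2.0, 2.0, 2.0),
        origin_mm=(0.0, 0.0, 0.0),
    )


class TestRadiologicalDepth:
    # Material boundaries sit at midpoints between voxel centres, so a
    # 3-voxel air margin puts the entry surface at y = 0.5 cm and the
    # first tissue centre half a voxel (0.1 cm) past it.

    def _water_with_air_margin(self):
        labels = np.zeros((21, 81, 9), dtype=np.int8)  # air
        labels[:, 3:, :] = Material.SOFT_TISSUE
        return MaterialMap(labels, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))

    def test_water_depth_equals_geometric_distance(self):
        materials = self._water_with_air_margin()
        # voxel centre at y = 5.6 cm, entry surface at 0.5 cm -> 5.1 cm
        d = radiological_depth(materials, BeamSpec(0.0), (10, 28, 4))
        assert d == pytest.approx(5.1, abs=0.03)

    def test_entry_voxel_depth_is_half_voxel(self):
        materials = self._water_with_air_margin()
        d = radiological_depth(materials, BeamSpec(0.0), (10, 3, 4))
        assert d == pytest.approx(0.1, abs=0.03)

    def test_bone_raises_water_equivalent_depth(self):
        labels = np.full((5, 80, 5), int(Material.BRAIN), dtype=np.int8)
        labels[:, :2, :] = Material.AIR
        labels[:, 2:7, :] = Material.BONE  # 1.0 cm slab (y 0.3 to 1.3)
        materials = MaterialMap(labels, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        # voxel centre y = 5.8 cm: 1 cm bone x 1.4 + 4.5 cm brain = 5.9
        d = radiological_depth(materials, BeamSpec(0.0), (2, 29, 2))
        assert d == pytest.approx(1.0 * 1.4 + 4.5 * 1.0, abs=0.03)
        # relabelling bone as brain removes exactly the 0.4 cm excess
        labels_water = labels.copy()
        labels_water[labels_water == Material.BONE] = Material.BRAIN
        water = MaterialMap(labels_water, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        d_geo = radiological_depth(water, BeamSpec(0.0), (2, 29, 2))
        assert d - d_geo == pytest.approx(0.4, abs=0.02)

    def test_map_agrees_with_single_voxel_march(self, phantom_seed1):
        materials, _ = phantom_seed1
        depth_map = dose_engine.radiological_depth_map(materials, 90.0)
        beam = BeamSpec(90.0)
        centre = tuple(s // 2 for s in materials.shape)
        assert depth_map[centre] == pytest.approx(
            radiological_depth(materials, beam, centre), abs=0.08
        )


class TestTraceField:
    def test_on_axis_values_match_depth_dose_closed_form(self):
        materials, structures = make_water_box(shape=(41, 121, 15), ctv="block")
        bm = BeamModelParams()
        out = trace_field(materials, structures, BeamSpec(0.0), bm)
        depth = dose_engine.radiological_depth_map(materials, 0.0)
        ix, iz = 20, 7  # beam axis through the CTV block centre
        for iy in (10, 40, 80):
            d = depth[ix, iy, iz]
            for name in ("thermal", "fast", "photon", "b10"):
                expected = component_depth_dose_rate(d, name, bm)
                assert out.component(name)[ix, iy, iz] == pytest.approx(
                    expected, rel=1e-6
                )

    def test_far_off_axis_is_dark(self, phantom_seed1, beam_defaults):
        materials, structures = phantom_seed1
        bm, _ = beam_defaults
        out = trace_field(materials, structures, BeamSpec(0.0), bm)
        x, y, z = (
            materials.origin_cm[a] + materials.spacing_cm[a] * np.arange(materials.shape[a])
            for a in range(3)
        )
        iso_x = 0.0  # CTV is laterally centred
        r = np.abs(x - iso_x)
        far = (r[:, None, None] > 12.0) & np.ones(materials.shape, bool)
        peak = out.thermal.max()
        for name in ("thermal", "fast", "photon", "b10"):
            assert np.all(out.component(name)[far] < 1e-4 * max(peak, 1e-12))

    def test_opposed_beams_mirror_symmetric(self):
        materials, structures = make_water_box(shape=(61, 61, 11), ctv="block")
        bm = BeamModelParams()
        left = trace_field(materials, structures, BeamSpec(90.0), bm)
        right = trace_field(materials, structures, BeamSpec(270.0), bm)
        for name in ("thermal", "fast", "photon", "b10"):
            np.testing.assert_allclose(
                left.component(name), right.component(name)[::-1, :, :],
                rtol=1e-6, atol=1e-12,
            )

    def test_field_missing_body_warns_and_zeroes(self):
        labels = np.zeros((11, 11, 5), dtype=np.int8)  # all air
        materials = MaterialMap(labels, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        body = np.zeros_like(labels, dtype=bool)
        ctv = np.zeros_like(body)
        ctv[5, 5, 2] = True
        structures = StructureSet(
            masks={"body": body, "ctv": ctv, "nb": body},
            spacing_mm=(2.0, 2.0, 2.0), origin_mm=(0.0, 0.0, 0.0),
        )
        with pytest.warns(UserWarning, match="misses the body"):
            out = trace_field(materials, structures, BeamSpec(0.0), BeamModelParams())
        assert not np.any(out.thermal) and not np.any(out.b10)


class TestDrsf:
    def test_adjustment_applies_published_factors_exactly(self):
        rb = RadiobiologyParams()
        raw = _unit_components((2, 1, 1))
        raw.fast *= 2.0
        adj = apply_drsf(raw, rb)
        assert adj.thermal[0, 0, 0] == 0.64
        assert adj.fast[0, 0, 0] == pytest.approx(2.78)
        assert adj.photon[0, 0, 0] == 0.96
        assert adj.b10[0, 0, 0] == 0.65
        assert adj.drsf_applied

    def test_unit_factors_are_identity(self):
        rb = RadiobiologyParams(drsf_thermal=1, drsf_fast=1, drsf_photon=1, drsf_b10=1)
        raw = _unit_components((3, 2, 1))
        adj = apply_drsf(raw, rb)
        for name in ("thermal", "fast", "photon", "b10"):
            np.testing.assert_array_equal(adj.component(name), raw.component(name))

    def test_double_application_refused(self):
        rb = RadiobiologyParams()
        adj = apply_drsf(_unit_components((1, 1, 1)), rb)
        with pytest.raises(DrsfAlreadyAppliedError):
            apply_drsf(adj, rb)


class TestBoronMap:
    def test_compartment_concentrations(self, phantom_seed1):
        _, structures = phantom_seed1
        rb = RadiobiologyParams()
        bmap = build_boron_map(structures, rb, ref_conc_ppm=25.0)
        conc = bmap.concentration_ppm
        assert np.all(conc[structures["ctv"]] == 25.0 * 3.5)
        normal = structures["body"] & ~structures["ctv"]
        assert np.all(conc[normal] == 25.0)
        assert np.all(conc[~structures["body"]] == 0.0)

    def test_mean_ratio_equals_tn(self, phantom_seed1):
        _, structures = phantom_seed1
        rb = RadiobiologyParams()
        bmap = build_boron_map(structures, rb)
        ctv_mean = bmap.concentration_ppm[structures["ctv"]].mean()
        nb_mean = bmap.concentration_ppm[structures["nb"]].mean()
        assert ctv_mean / nb_mean == pytest.approx(3.5, rel=1e-12)

    def test_unit_tn_is_uniform_in_body(self, phantom_seed1):
        _, structures = phantom_seed1
        rb = RadiobiologyParams(tn_ratio=1.0)
        bmap = build_boron_map(structures, rb, 30.0)
        assert np.all(bmap.concentration_ppm[structures["body"]] == 30.0)


class TestRbeWeighting:
    def test_linearity_in_beam_minutes(self):
        structures = _two_voxel_structures()
        rb = RadiobiologyParams()
        adj = _unit_components((2, 1, 1), drsf_applied=True)
        adj.thermal[1] = 0.3
        boron = BoronMap(np.full((2, 1, 1), 25.0), 25.0)
        one = rbe_weighted_dose(adj, boron, structures, rb, beam_minutes=1.0)
        two = rbe_weighted_dose(adj, boron, structures, rb, beam_minutes=2.0)
        np.testing.assert_allclose(two.dose_gy_eq, 2.0 * one.dose_gy_eq, rtol=1e-15)

    def test_boron_term_scales_with_local_concentration(self):
        structures = _two_voxel_structures()
        rb = RadiobiologyParams()
        adj = _unit_components((2, 1, 1), drsf_applied=True)
        ref = BoronMap(np.full((2, 1, 1), 25.0), 25.0)
        double = BoronMap(np.full((2, 1, 1), 50.0), 25.0)
        base = rbe_weighted_dose(adj, ref, structures, rb).dose_gy_eq
        up = rbe_weighted_dose(adj, double, structures, rb).dose_gy_eq
        # only the boron term doubles: +CBE per voxel
        assert up[0, 0, 0] - base[0, 0, 0] == pytest.approx(rb.cbe_tumor)
        assert up[1, 0, 0] - base[1, 0, 0] == pytest.approx(rb.cbe_brain)

    def test_zero_components_give_zero_dose(self):
        structures = _two_voxel_structures()
        rb = RadiobiologyParams()
        zeros = np.zeros((2, 1, 1))
        adj = ComponentDoseMap(zeros, zeros.copy(), zeros.copy(), zeros.copy(),
                               drsf_applied=True)
        boron = BoronMap(np.full((2, 1, 1), 25.0), 25.0)
        assert np.all(rbe_weighted_dose(adj, boron, structures, rb).dose_gy_eq == 0.0)

    def test_mismatched_grids_rejected(self):
        structures = _two_voxel_structures()
        rb = RadiobiologyParams()
        adj = _unit_components((3, 1, 1), drsf_applied=True)
        boron = BoronMap(np.full((3, 1, 1), 25.0), 25.0)
        with pytest.raises(DoseGridMismatchError):
            rbe_weighted_dose(adj, boron, structures, rb)


def test_superposition_of_fields(phantom_seed1, beam_defaults):
    """Multi-field RBE dose equals the sum of single-field doses."""
    materials, structures = phantom_seed1
    bm, rb = beam_defaults
    boron = build_boron_map(structures, rb, bm.reference_boron_ppm)
    maps = [
        dose_engine.field_rbe_rate_map(materials, structures, BeamSpec(a), bm, rb, boron=boron)
        for a in (90.0, 270.0)
    ]
    combined = 3.0 * maps[0] + 5.0 * maps[1]
    resummed = sum(m * t for m, t in zip(maps, (3.0, 5.0)))
    np.testing.assert_allclose(combined, resummed, rtol=1e-12)


def test_engine_and_beam_model_agree_on_advantage_depth(beam_defaults):
    """On-axis tumor/normal curves in a water slab cross at the AD."""
    bm, rb = beam_defaults
    materials, structures_all = make_water_box(shape=(41, 121, 15), ctv="all")
    _, structures_none = make_water_box(shape=(41, 121, 15), ctv="none")
    iso = np.array([4.0, 12.0, 1.4])  # on the 0-degree axis, mid-slab
    tumor = dose_engine.field_rbe_rate_map(
        materials, structures_all, BeamSpec(0.0), bm, rb, isocenter_cm=iso
    )
    normal = dose_engine.field_rbe_rate_map(
        materials, structures_none, BeamSpec(0.0), bm, rb, isocenter_cm=iso
    )
    ix, iz = 20, 7
    t_axis = tumor[ix, :, iz]
    n_axis = normal[ix, :, iz]
    n_max = n_axis.max()
    crossing_idx = np.nonzero(t_axis >= n_max)[0][-1]
    depth = dose_engine.radiological_depth_map(materials, 0.0)[ix, crossing_idx, iz]
    assert depth == pytest.approx(compute_advantage_depth(bm, rb), abs=0.15)
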