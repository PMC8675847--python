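"""Phantom/mouse generators and the linear forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dectquant import (
    Grid,
    MaterialMaps,
    MouseScenario,
    PhantomSpec,
    ScanProtocol,
    SensitivityMatrix,
    build_mouse,
    build_phantom,
    forward_project,
    vial_label_volume,
)
from dectquant.exceptions import ConfigurationError, GeometryError
from dectquant.synthetic import MOUSE_ORGANS, default_mouse_geometry

from conftest import EXAMPLE_SENSITIVITY, VIAL_CONCS_UG


class TestPhantom:
    def test_vial_voxels_carry_nominal_concentrations_in_mg_ml(
        self, phantom_truth, vial_labels
    ):
        for k, conc_ug in enumerate(VIAL_CONCS_UG, start=1):
            vals = phantom_truth.c_au[vial_labels == k]
            assert vals.size > 0
            np.testing.assert_allclose(vals, conc_ug / 1000.0)

    def test_background_and_outside_have_zero_gold(self, phantom_truth, vial_labels):
        assert np.all(phantom_truth.c_au[vial_labels == 0] == 0.0)
        assert np.all(phantom_truth.c_water[~phantom_truth.mask] == 0.0)

    def test_zero_concentration_vial_matches_water_background(self):
        spec = PhantomSpec(vial_concentrations=(0.0,), background_material="water")
        maps = build_phantom(spec)
        labels = vial_label_volume(spec)
        assert np.all(maps.c_au == 0.0)
        # water vial in a water body: indistinguishable in both materials
        np.testing.assert_allclose(maps.c_water[labels == 1], 1000.0)
        np.testing.assert_allclose(maps.c_water[maps.mask & (labels == 0)], 1000.0)

    def test_overlapping_vials_raise_geometry_error(self):
        spec = PhantomSpec(
            vial_concentrations=(250.0, 500.0),
            vial_centres=((0.0, 0.0), (3.0, 0.0)),  # 3 mm apart, radius 4
        )
        with pytest.raises(GeometryError, match="overlap"):
            build_phantom(spec)

    def test_vial_outside_body_raises_geometry_error(self):
        spec = PhantomSpec(
            vial_concentrations=(250.0,), vial_centres=((29.0, 0.0),), vial_radius=4.0
        )
        with pytest.raises(GeometryError, match="outside"):
            vial_label_volume(spec)


class TestMouse:
    def test_targeting_doubles_tumour_only(self):
        scen = MouseScenario(targeting_ratio=2.0)
        nt, geo = build_mouse(scen, targeted=False)
        t, _ = build_mouse(scen, targeted=True)
        np.testing.assert_allclose(
            t.c_au[geo.mask("tumour")], 2.0 * nt.c_au[geo.mask("tumour")]
        )
        other = geo.body_mask & ~geo.mask("tumour")
        np.testing.assert_array_equal(t.c_au[other], nt.c_au[other])

    def test_unit_targeting_ratio_is_identity(self):
        scen = MouseScenario(targeting_ratio=1.0)
        nt, _ = build_mouse(scen, targeted=False)
        t, _ = build_mouse(scen, targeted=True)
        np.testing.assert_array_equal(t.c_au, nt.c_au)

    def test_unknown_organ_raises_configuration_error(self):
        scen = MouseScenario(organ_concentrations={"pancreas": 100.0})
        with pytest.raises(ConfigurationError, match="pancreas"):
            build_mouse(scen)

    def test_default_geometry_has_all_seven_disjoint_organs(self):
        geo = default_mouse_geometry()
        assert set(geo.label_ids) == set(MOUSE_ORGANS)
        total = 0
        for organ in MOUSE_ORGANS:
            n = int(geo.mask(organ).sum())
            assert n >= 1, organ
            total += n
        # labels partition organs: per-organ masks cannot overlap
        assert total == int((geo.label_map >= 2).sum())

    def test_tumour_volume_is_one_tenth_cm3(self):
        geo = default_mouse_geometry()
        voxel_mm3 = np.prod(geo.grid.voxel_size)
        vol = geo.mask("tumour").sum() * voxel_mm3
        assert vol == pytest.approx(100.0, rel=0.05)  # 0.1 cm^3 in mm^3


class TestForwardModel:
    def test_pure_water_baseline_is_zero_hu(self):
        maps = MaterialMaps(
            c_water=np.full((4, 4, 2), 1000.0),
            c_au=np.zeros((4, 4, 2)),
            mask=np.ones((4, 4, 2), bool),
        )
        img = forward_project(maps, EXAMPLE_SENSITIVITY, ScanProtocol(noise_sd=0.0))
        np.testing.assert_allclose(img.ct_low, 1000.0)
        np.testing.assert_allclose(img.hu_high, 0.0)

    def test_hand_evaluated_linear_response(self):
        # (c_water, c_au) = (1000, 2) under slopes (5, 7) -> CT' = (1010, 1014)
        maps = MaterialMaps(
            c_water=np.full((2, 2, 1), 1000.0),
            c_au=np.full((2, 2, 1), 2.0),
            mask=np.ones((2, 2, 1), bool),
        )
        img = forward_project(maps, EXAMPLE_SENSITIVITY, ScanProtocol(noise_sd=0.0))
        np.testing.assert_allclose(img.ct_low, 1010.0)
        np.testing.assert_allclose(img.ct_high, 1014.0)

    def test_fixed_seed_is_bit_identical(self, phantom_truth):
        protocol = ScanProtocol(noise_sd=8.0, seed=42)
        a = forward_project(phantom_truth, protocol=protocol)
        b = forward_project(phantom_truth, protocol=protocol)
        np.testing.assert_array_equal(a.ct_low, b.ct_low)
        np.testing.assert_array_equal(a.ct_high, b.ct_high)

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(0.0, 5.0),
        b=st.floats(0.0, 5.0),
        cw=st.floats(0.0, 1200.0),
    )
    def test_noiseless_response_is_affine_in_gold(self, a, b, cw):
        """CT'(c_au = a+b) - CT'(c_au = a) = e_Au * b exactly, per energy."""
        def ct(c_au):
            maps = MaterialMaps(
                c_water=np.full((1, 1, 1), cw),
                c_au=np.full((1, 1, 1), c_au),
                mask=np.ones((1, 1, 1), bool),
            )
            img = forward_project(maps, EXAMPLE_SENSITIVITY, ScanProtocol(noise_sd=0.0))
            return np.array([img.ct_low[0, 0, 0], img.ct_high[0, 0, 0]])

        delta = ct(a + b) - ct(a)
        np.testing.assert_allclose(delta, [5.0 * b, 7.0 * b], atol=1e-9)

    def test_response_strictly_increases_with_gold(self):
        concs = np.linspace(0.0, 3.0, 7)
        cts = []
        for c in concs:
            maps = MaterialMaps(
                c_water=np.full((1, 1, 1), 1000.0),
                c_au=np.full((1, 1, 1), c),
                mask=np.ones((1, 1, 1), bool),
            )
            img = forward_project(maps, EXAMPLE_SENSITIVITY, ScanProtocol(noise_sd=0.0))
            cts.append((img.ct_low.item(), img.ct_high.item()))
        cts = np.array(cts)
        assert np.all(np.diff(cts[:, 0]) > 0)
        assert np.all(np.diff(cts[:, 1]) > 0)


class TestProtocolValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"energy_low": 140.0, "energy_high": 80.0},
            {"noise_sd": -1.0},
            {"voxel_size": (1.0, 0.0, 1.0)},
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScanProtocol(**kwargs)

    def test_scalar_noise_sd_broadcasts_to_both_energies(self):
        assert ScanProtocol(noise_sd=3.0).noise_sd == (3.0, 3.0)
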