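"""Transition-function values, composition algebra and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memgeom as mg
from memgeom.geometry import geometry_field

from conftest import finite_difference_gradient

TP = mg.TransitionParams()


class TestSlab:
    @pytest.mark.parametrize("z, expected", [
        (0.0, 0.0),            # membrane centre is fully hydrophobic
        (15.0, 0.5),           # midpoint of the transition at depth t
        (-15.0, 0.5),
    ])
    def test_reference_values(self, z, expected):
        assert mg.f_thk_slab(z, TP) == pytest.approx(expected, abs=1e-12)

    def test_bulk_water_limit(self):
        assert mg.f_thk_slab(1e4 * TP.half_thickness, TP) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_and_monotone_in_depth(self):
        z = np.linspace(0, 60, 200)
        f = mg.f_thk_slab(z, TP)
        assert np.array_equal(f, mg.f_thk_slab(-z, TP))
        assert np.all(np.diff(f) >= 0)

    def test_nonfinite_depth_rejected(self):
        with pytest.raises(ValueError):
            mg.f_thk_slab(np.nan, TP)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mg.TransitionParams(half_thickness=-1)
        with pytest.raises(ValueError):
            mg.TransitionParams(steepness=0)


class TestEllipsoid:
    def test_micelle_center_is_hydrophobic(self):
        assert mg.f_ellipsoid(np.zeros(3), mg.GeometrySpec.micelle(), TP) == 0.0

    def test_micelle_outer_surface_in_plane(self):
        # on the outer-radius sphere at z=0 the radial factor alone gives 0.5
        geom = mg.GeometrySpec.micelle()
        outer = geom.ellipsoid_outer_radius(TP)
        assert mg.f_ellipsoid([outer, 0.0, 0.0], geom, TP) == pytest.approx(0.5)

    def test_deep_water_fixed_point(self):
        # wherever the slab factor is 1 the composition is 1 regardless of h
        geom = mg.GeometrySpec.ellipsoid(50.0)
        assert mg.f_ellipsoid([0.0, 0.0, 5e4], geom, TP) == pytest.approx(1.0, abs=1e-9)

    def test_micelle_is_ellipsoid_with_zero_inner_radius(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(-40, 40, (500, 3))
        a = mg.f_ellipsoid(pos, mg.GeometrySpec.ellipsoid(0.0), TP)
        b = mg.f_ellipsoid(pos, mg.GeometrySpec.micelle(), TP)
        assert np.array_equal(a, b)

    def test_radial_factor_constant_over_planar_disc(self):
        # the lateral distance is measured from the disc edge, so every
        # point of the planar section (z=0, rho <= inner_radius) sees the
        # same radial factor: the core is flat
        geom = mg.GeometrySpec.ellipsoid(50.0)
        rho = np.linspace(0.0, 50.0, 25)
        pos = np.column_stack([rho, np.zeros_like(rho), np.zeros_like(rho)])
        f = mg.f_ellipsoid(pos, geom, TP)
        assert np.ptp(f) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            mg.GeometrySpec.ellipsoid(-5.0)
        with pytest.raises(ValueError):
            mg.GeometrySpec.ellipsoid(10.0, outer_radius=-1.0)


class TestVesicle:
    def test_origin_on_mid_surface(self):
        for radius in (60.0, 120.0, 1e6):
            geom = mg.GeometrySpec.vesicle(radius)
            assert mg.f_vesicle(np.zeros(3), geom, TP) == 0.0

    def test_curvature_sign_places_center(self):
        down = mg.GeometrySpec.vesicle(120.0, "down")
        up = mg.GeometrySpec.vesicle(120.0, "up")
        assert np.allclose(down.sphere_center(TP), [0, 0, -120.0])
        assert np.allclose(up.sphere_center(TP), [0, 0, 120.0])
        # an off-centre probe distinguishes the two curvature directions
        probe = np.array([30.0, 0.0, 5.0])
        assert mg.f_vesicle(probe, down, TP) != mg.f_vesicle(probe, up, TP)

    def test_flat_limit_matches_slab(self):
        geom = mg.GeometrySpec.vesicle(1e6)
        rng = np.random.default_rng(5)
        pos = rng.uniform(-25, 25, (2000, 3))
        diff = mg.f_vesicle(pos, geom, TP) - mg.f_thk_slab(pos[:, 2], TP)
        assert np.abs(diff).max() < 1e-4

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            mg.GeometrySpec.vesicle(0.0)


class TestDoubleVesicle:
    GEOM = mg.GeometrySpec.double_vesicle(1000.0, 40.0)

    def test_reported_gap_junction_settings_accepted(self):
        assert self.GEOM.dv_inner_radius == 1000.0
        assert self.GEOM.dv_distance == 40.0

    def test_inner_mid_surface_is_hydrophobic(self):
        center = self.GEOM.sphere_center(TP)
        pos = center + np.array([0.0, 0.0, self.GEOM.dv_inner_radius])
        assert mg.f_double_vesicle(pos, self.GEOM, TP) == 0.0

    def test_wide_gap_midpoint_is_aqueous(self):
        t = TP.half_thickness
        geom = mg.GeometrySpec.double_vesicle(5000.0, 200.0 * t)
        # origin sits midway between the membranes by construction
        f = mg.f_double_vesicle(np.zeros(3), geom, TP)
        assert f == pytest.approx(1.0, abs=1e-3)
        # and equals the product of the two single-vesicle fields
        center = geom.sphere_center(TP)
        r = np.linalg.norm(center)
        f1 = mg.f_thk_slab(r - geom.dv_inner_radius, TP)
        f2 = mg.f_thk_slab(r - geom.dv_outer_surface_radius(TP), TP)
        assert f == pytest.approx(f1 * f2)

    def test_flat_limit_matches_two_slab_product(self):
        geom = mg.GeometrySpec.double_vesicle(1e6, 40.0)
        rng = np.random.default_rng(6)
        pos = rng.uniform(-25, 25, (2000, 3))
        t, d = TP.half_thickness, 40.0
        z_mid = t + d / 2.0  # flat membranes centred at -+z_mid
        expected = (mg.f_thk_slab(pos[:, 2] + z_mid, TP)
                    * mg.f_thk_slab(pos[:, 2] - z_mid, TP))
        diff = mg.f_double_vesicle(pos, geom, TP) - expected
        assert np.abs(diff).max() < 1e-4

    def test_membranes_cannot_overlap(self):
        # edge-to-edge distance definition: outer mid-surface >= inner + 2t
        for d in (0.0, 10.0, 300.0):
            geom = mg.GeometrySpec.double_vesicle(500.0, d)
            gap = geom.dv_outer_surface_radius(TP) - geom.dv_inner_radius
            assert gap >= 2.0 * TP.half_thickness

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mg.GeometrySpec.double_vesicle(0.0, 40.0)
        with pytest.raises(ValueError):
            mg.GeometrySpec.double_vesicle(1000.0, -1.0)


class TestPore:
    PORE = mg.PoreSpec(radius=5.0)

    @pytest.mark.parametrize("pos, expected", [
        ([0.0, 0.0, 0.0], 1.0),     # on the axis
        ([5.0, 0.0, 0.0], 0.5),     # at the pore radius
        ([5000.0, 0.0, 0.0], 0.0),  # far away
    ])
    def test_reference_values(self, pos, expected):
        assert mg.f_cavity(np.array(pos), self.PORE) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_lateral_distance(self):
        rho = np.linspace(0, 50, 300)
        pos = np.column_stack([rho, np.zeros_like(rho), np.zeros_like(rho)])
        f = mg.f_cavity(pos, self.PORE)
        assert np.all(np.diff(f) <= 0)

    def test_off_axis_pore_center(self):
        pore = mg.PoreSpec(radius=5.0, center_x=10.0, center_y=-3.0)
        assert mg.f_cavity([10.0, -3.0, 7.0], pore) == pytest.approx(1.0)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            mg.PoreSpec(radius=0.0)


class TestComposePore:
    @pytest.mark.parametrize("f_thk, f_cav, expected", [
        (0.0, 0.0, 0.0),
        (1.0, 0.3, 1.0),   # 1 absorbs
        (0.7, 1.0, 1.0),
        (0.5, 0.5, 0.75),
        (0.25, 0.0, 0.25),  # 0 is the identity
    ])
    def test_reference_values(self, f_thk, f_cav, expected):
        assert mg.compose_pore(f_thk, f_cav) == pytest.approx(expected)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_union_algebra(self, a, b):
        out = float(mg.compose_pore(a, b))
        assert 0.0 <= out <= 1.0
        assert out >= max(a, b) - 1e-15
        assert out == pytest.approx(float(mg.compose_pore(b, a)))

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            mg.compose_pore(-0.1, 0.5)
        with pytest.raises(ValueError):
            mg.compose_pore(0.5, 1.2)


class TestHydration:
    def test_single_atom_slab(self):
        res = mg.hydration(np.zeros((1, 3)), mg.GeometrySpec.slab())
        assert res.f_hyd[0] == 0.0

    def test_pore_axis_overrides_membrane(self):
        res = mg.hydration(np.zeros((1, 3)), mg.GeometrySpec.slab(),
                           pore=mg.PoreSpec(radius=5.0))
        assert res.f_hyd[0] == pytest.approx(1.0)
        assert res.f_thk[0] == 0.0 and res.f_cavity[0] == pytest.approx(1.0)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            mg.hydration(np.zeros((0, 3)), mg.GeometrySpec.slab())

    def test_micelle_identity_on_structure(self, tm_helix):
        st_, _ = tm_helix
        a = mg.hydration(st_, mg.GeometrySpec.ellipsoid(0.0)).f_hyd
        b = mg.hydration(st_, mg.GeometrySpec.micelle()).f_hyd
        assert np.array_equal(a, b)

    def test_values_in_unit_interval_all_geometries(self, all_geometries):
        rng = np.random.default_rng(9)
        pos = rng.uniform(-200, 200, (5000, 3))
        pore = mg.PoreSpec(radius=rng.uniform(2, 10))
        for geom in all_geometries.values():
            tp = mg.TransitionParams(half_thickness=rng.uniform(10, 20),
                                     steepness=rng.uniform(2, 14))
            res = mg.hydration(pos, geom, pore, tp)
            for arr in (res.f_thk, res.f_cavity, res.f_hyd):
                assert np.all((arr >= 0) & (arr <= 1))

    def test_ellipsoid_stores_radial_factor(self):
        res = mg.hydration(np.zeros((1, 3)), mg.GeometrySpec.ellipsoid(20.0))
        assert res.h_radial is not None
        assert mg.hydration(np.zeros((1, 3)), mg.GeometrySpec.slab()).h_radial is None


class TestGradients:
    def test_slab_gradient_is_axial(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-30, 30, (100, 3))
        g = mg.gradient_f_hyd(pos, mg.GeometrySpec.slab())
        assert np.all(g[:, :2] == 0.0)

    def test_slab_gradient_vanishes_at_center(self):
        g = mg.gradient_f_hyd(np.zeros((1, 3)), mg.GeometrySpec.slab())
        assert np.all(g == 0.0)

    def test_vesicle_center_defined_zero_with_warning(self):
        geom = mg.GeometrySpec.vesicle(120.0)
        center = geom.sphere_center(TP)
        with pytest.warns(UserWarning):
            g = mg.gradient_f_hyd(center[None, :], geom)
        assert np.all(g == 0.0)

    @pytest.mark.parametrize("with_pore", [False, True])
    def test_matches_finite_differences(self, all_geometries, with_pore):
        rng = np.random.default_rng(17)
        pore = mg.PoreSpec(radius=5.0) if with_pore else None
        for geom in all_geometries.values():
            pos = rng.uniform(-45, 45, (400, 3))

            def field(p, geom=geom):
                f = geometry_field(p, geom, TP)
                if pore is not None:
                    f = mg.compose_pore(f, mg.f_cavity(p, pore))
                return f

            fd = finite_difference_gradient(field, pos)
            ana = mg.gradient_f_hyd(pos, geom, pore, TP)
            mag = np.linalg.norm(fd, axis=1)
            keep = mag > 1e-3  # informative points: inside the transition shell
            assert keep.sum() > 20
            rel = np.linalg.norm(ana[keep] - fd[keep], axis=1) / mag[keep]
            assert rel.max() < 1e-6
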