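import numpy as np
import pytest

from octmech.cohort import CohortConfig, GroupParams, generate_lesion
from octmech.fea import (MaterialProperties, SimulationConfig, build_mesh,
                         default_materials, lame_annulus_reference,
                         material_variants, solve_elasticity, von_mises)
from octmech.metrics import stress_summary
from .conftest import make_cap_lesion


class TestVonMises:
    @pytest.mark.parametrize("s,expected", [
        ((100, 0, 0, 0), 100.0),          # uniaxial
        ((50, 50, 50, 0), 0.0),           # hydrostatic
        ((0, 0, 0, 10), 10 * np.sqrt(3)),  # pure shear
    ])
    def test_reference_states(self, s, expected):
        sxx, syy, szz, txy = s
        assert von_mises(sxx, syy, szz, txy) == pytest.approx(expected)

    def test_nonnegative_on_random_states(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(4, 100)) * 100
        assert np.all(von_mises(*s) >= 0)


class TestMaterials:
    def test_defaults_are_the_published_table(self):
        m = default_materials()
        assert m["cap"] == (244e3, 0.27)
        assert m["lipid"] == (1e3, 0.48)
        assert m["calcification"] == (10e9, 0.30)
        assert m["wall"] == (800e3, 0.27)

    @pytest.mark.parametrize("variant,region,expected", [
        ("wall_incompressible", "wall", (800e3, 0.48)),
        ("soft_calcification", "calcification", (10e6, 0.30)),
        ("bone_calcification", "calcification", (20e9, 0.30)),
    ])
    def test_named_variants(self, variant, region, expected):
        base = default_materials()
        out = material_variants(base, variant)
        assert out[region] == expected
        # base untouched
        assert default_materials()[region] == base[region]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            material_variants(default_materials(), "rubber_wall")

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            MaterialProperties({"wall": (-1.0, 0.3)})
        with pytest.raises(ValueError):
            MaterialProperties({"wall": (1e5, 0.5)})


class TestLameOracle:
    def test_boundary_conditions_exact(self):
        ora = lame_annulus_reference(1.0, 2.0, 800e3, 0.27, 17.0)
        assert ora.sigma_rr(1.0) == pytest.approx(-17.0, rel=1e-12)
        assert ora.u(2.0) == pytest.approx(0.0, abs=1e-15)

    def test_plane_strain_szz_relation(self):
        ora = lame_annulus_reference(1.0, 2.0, 800e3, 0.27, 17.0)
        r = np.linspace(1.0, 2.0, 7)
        assert np.allclose(ora.sigma_zz(r),
                           0.27 * (ora.sigma_rr(r) + ora.sigma_theta(r)))

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            lame_annulus_reference(2.0, 1.0, 800e3, 0.27, 17.0)


@pytest.fixture(scope="module")
def annulus_errors(annulus_geometry, wall_material):
    """Max relative von Mises error vs the analytic solution per refinement."""
    ora = lame_annulus_reference(1.0, 2.0, 800e3, 0.27, 17.0)
    errs = {}
    for level in ("coarse", "fine", "very_fine"):
        cfg = SimulationConfig(refinement=level)
        mesh = build_mesh(annulus_geometry, cfg)
        fld = solve_elasticity(mesh, wall_material, cfg)
        r = np.linalg.norm(mesh.element_centroids(), axis=1)
        ref = ora.von_mises(r)
        errs[level] = float(np.max(np.abs(fld.vm - ref)) / np.max(ref))
    return errs


class TestSolverVsAnalytic:
    def test_error_below_one_percent_at_very_fine(self, annulus_errors):
        assert annulus_errors["very_fine"] < 0.01

    def test_monotone_convergence(self, annulus_errors):
        assert (annulus_errors["coarse"] > annulus_errors["fine"]
                > annulus_errors["very_fine"])

    def test_single_material_mesh_all_wall(self, annulus_geometry):
        mesh = build_mesh(annulus_geometry, SimulationConfig())
        assert set(mesh.element_regions()) == {"wall"}
        assert mesh.min_corner_angle_deg > 0


class TestSolverBasics:
    def test_zero_pressure_zero_field(self, annulus_geometry, wall_material):
        cfg = SimulationConfig(pressure_kpa=0.0, refinement="coarse")
        mesh = build_mesh(annulus_geometry, cfg)
        fld = solve_elasticity(mesh, wall_material, cfg)
        assert np.allclose(fld.displacement, 0.0)
        assert np.allclose(fld.vm, 0.0)

    def test_linearity_in_pressure(self, annulus_geometry, wall_material):
        cfg1 = SimulationConfig(pressure_kpa=17.0, refinement="coarse")
        cfg2 = SimulationConfig(pressure_kpa=34.0, refinement="coarse")
        mesh = build_mesh(annulus_geometry, cfg1)
        f1 = solve_elasticity(mesh, wall_material, cfg1)
        f2 = solve_elasticity(mesh, wall_material, cfg2)
        assert np.allclose(f2.vm, 2 * f1.vm, rtol=1e-9)
        assert np.allclose(f2.displacement, 2 * f1.displacement, rtol=1e-9)

    def test_plane_strain_szz_invariant(self, solved_lesion):
        _, mesh, fld, _ = solved_lesion
        nus = {"cap": 0.27, "lipid": 0.48, "calcification": 0.30, "wall": 0.27}
        nu = np.array([nus[r] for r in mesh.element_regions()])
        assert np.allclose(fld.szz, nu * (fld.sxx + fld.syy), atol=1e-9)

    def test_missing_material_raises(self, annulus_geometry):
        cfg = SimulationConfig(refinement="coarse")
        mesh = build_mesh(annulus_geometry, cfg)
        with pytest.raises(ValueError, match="wall"):
            solve_elasticity(mesh, MaterialProperties({"cap": (1e5, 0.3)}),
                             cfg)


class TestMultiMaterialMesh:
    def test_region_partition_audited_by_point_in_polygon(self, thinned_lesion):
        from shapely.geometry import Point
        mesh = build_mesh(thinned_lesion, SimulationConfig())
        cent = mesh.element_centroids()
        regions = mesh.element_regions()
        lipid_poly = thinned_lesion.lipid_cores[0].polygon()
        inside = np.array([lipid_poly.contains(Point(*p)) for p in cent])
        # every element centroid inside the lipid polygon is labelled lipid
        # and vice versa (boundary-conforming partition)
        assert np.array_equal(inside, regions == "lipid")
        assert {"cap", "lipid", "wall"} <= set(regions)

    def test_halving_edge_length_quadruples_elements(self, annulus_geometry):
        n_fine = build_mesh(annulus_geometry,
                            SimulationConfig(refinement="fine")).n_elements
        n_vf = build_mesh(annulus_geometry,
                          SimulationConfig(refinement="very_fine")).n_elements
        assert n_vf / n_fine == pytest.approx(4.0, rel=0.25)

    def test_degenerate_cap_rejected(self):
        geom = make_cap_lesion(cap_um=100.0)
        geom.cap_outer = geom.lumen   # zero-width cap
        with pytest.raises(ValueError, match="cap"):
            build_mesh(geom, SimulationConfig())


class TestFrameInvariance:
    def test_rotation_rotates_field_but_not_von_mises(self, thinned_lesion):
        cfg = SimulationConfig()
        mats = default_materials()
        mesh0 = build_mesh(thinned_lesion, cfg)
        f0 = solve_elasticity(mesh0, mats, cfg)
        s0 = stress_summary(f0, mesh0, thinned_lesion)
        rot = thinned_lesion.transformed(rotation_deg=30.0)
        mesh1 = build_mesh(rot, cfg)
        f1 = solve_elasticity(mesh1, mats, cfg)
        s1 = stress_summary(f1, mesh1, rot)
        assert s1.peak_cap_stress == pytest.approx(s0.peak_cap_stress,
                                                   rel=0.01)
        assert s1.maximal_plaque_stress == pytest.approx(
            s0.maximal_plaque_stress, rel=0.01)
        shift = (s1.pcs_angle - s0.pcs_angle) % 360.0
        assert min(shift, 360 - shift) == pytest.approx(30.0, abs=5.0)


class TestThinCapAmplification:
    def test_peak_cap_stress_grows_superlinearly_as_cap_thins(self):
        # same lesion except for the minimal cap thickness
        pcs = []
        for fct in (200.0, 150.0, 100.0, 50.0):
            cfg = CohortConfig(n_per_group=1, seed=5, lumen_waviness=0.0)
            cfg.groups["vulnerable"] = GroupParams(
                min_fct_um=(fct, 0.0), cap_max_um=(250.0, 0.0),
                max_lipid_arc_deg=(150.0, 0.0), lipid_length_mm=(40.0, 0.0),
                lipid_depth_mm=(0.4, 0.0), lumen_radius_mm=(1.0, 0.0),
                macrophage_prob=0.0, spotty_calc_prob=0.0)
            rng = np.random.default_rng(5)
            les = generate_lesion("vulnerable", cfg, rng)
            sim = SimulationConfig()
            mesh = build_mesh(les.geometry, sim)
            fld = solve_elasticity(mesh, default_materials(), sim)
            pcs.append(stress_summary(fld, mesh, les.geometry).peak_cap_stress)
        assert all(b > a for a, b in zip(pcs, pcs[1:]))
        # super-linear: the last 50 um of thinning raises stress more than
        # the first 50 um
        assert pcs[3] - pcs[2] > pcs[1] - pcs[0]
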