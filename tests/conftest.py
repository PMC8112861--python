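import numpy as np
import pytest

from octmech.cohort import CohortConfig, generate_cohort
from octmech.fea import (MaterialProperties, SimulationConfig, build_mesh,
                         default_materials, solve_elasticity)
from octmech.geometry import Contour, PlaqueCrossSection, circle_contour


@pytest.fixture(scope="session")
def annulus_geometry():
    """Homogeneous annulus a=1 mm, b=2 mm (the analytic reference case)."""
    return PlaqueCrossSection(lumen=circle_contour(1.0, n=512),
                              outer_wall=circle_contour(2.0, n=512))


@pytest.fixture(scope="session")
def wall_material():
    return MaterialProperties({"wall": (800e3, 0.27)})


def make_cap_lesion(r_lumen=1.0, cap_um=100.0, thin_um=None, sector=(45.0, 135.0),
                    lipid_depth=0.3, n=720):
    """Concentric lesion with a uniform cap, optionally thinned over a sector.

    The lipid core fills the sector between the (locally thinned) cap outer
    boundary and ``cap + lipid_depth``; used as an analytically tractable
    fixture for thickness-profile and FEA tests.
    """
    th_deg = np.arange(n) * (360.0 / n)
    th = np.radians(th_deg)
    t = np.full(n, cap_um / 1000.0)
    a0, a1 = sector
    mid = (a0 + a1) / 2
    arc = a1 - a0
    if thin_um is not None:
        d = (th_deg - mid + 180.0) % 360.0 - 180.0
        w = np.where(np.abs(d) <= arc / 2, np.cos(np.pi * d / arc) ** 2, 0.0)
        t = t - (cap_um - thin_um) / 1000.0 * w
    r_cap = r_lumen + t
    lumen = circle_contour(r_lumen, n=n)
    cap = Contour(np.column_stack([r_cap * np.cos(th), r_cap * np.sin(th)]))
    n_arc = max(32, int(arc / 360 * n))
    sth = np.linspace(a0, a1, n_arc)
    r_in = np.interp(sth % 360.0, th_deg, r_cap, period=360.0)
    r_out = r_in + lipid_depth
    sr = np.radians(sth)
    inner = np.column_stack([r_in * np.cos(sr), r_in * np.sin(sr)])
    outer = np.column_stack([r_out * np.cos(sr), r_out * np.sin(sr)])
    lipid = Contour(np.vstack([inner, outer[::-1]]))
    return PlaqueCrossSection(lumen=lumen, outer_wall=circle_contour(2.0, n=n),
                              cap_outer=cap, lipid_cores=[lipid])


@pytest.fixture(scope="session")
def thinned_lesion():
    """100 um cap thinned to 50 um over the 45-135 deg sector."""
    return make_cap_lesion(cap_um=100.0, thin_um=50.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-lesion cohort (3 per group) from a frozen seed."""
    return generate_cohort(CohortConfig(n_per_group=3, seed=11))


@pytest.fixture(scope="session")
def solved_lesion(small_cohort):
    """One solved vulnerable lesion: (lesion, mesh, field, summary)."""
    from octmech.metrics import stress_summary
    les = next(l for l in small_cohort if l.group == "vulnerable")
    sim = SimulationConfig()
    mesh = build_mesh(les.geometry, sim)
    fld = solve_elasticity(mesh, default_materials(), sim)
    summ = stress_summary(fld, mesh, les.geometry)
    return les, mesh, fld, summ
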