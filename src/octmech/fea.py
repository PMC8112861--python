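"""Plane-strain linear-elastic finite elements for plaque cross-sections.

The vessel is modelled as a long extruded cylinder loaded by a static
luminal pressure; evaluated away from its ends, the extrusion is exactly
the 2-D plane-strain problem, so the cross-section is solved directly in
2-D.  Displacements are small (order 10% of the lumen radius at
physiologic pressure), justifying the linear kinematics; the pressure is
applied as a traction on the undeformed lumen boundary and the outer wall
circle is fully fixed.

Meshing uses a structured banded polar grid of 6-node quadratic triangles:
rings follow the material interfaces (lumen boundary, cap outer boundary,
inclusion outer boundary) and spokes are snapped to inclusion sector
edges, so every element lies wholly in one material region and region
boundaries are element edges.  The mesher supports cross-sections that
are star-shaped about the lumen centroid with radially-contiguous
inclusions (lipid cores, calcifications) attached to the outer side of
the fibrous cap — the geometry class produced by the synthetic-lesion
generator and, to good approximation, by OCT segmentations of
non-dissected plaques.  Quadratic elements are used for stress accuracy
at bimaterial interfaces and to mitigate volumetric locking in the
nearly-incompressible lipid core (nu = 0.48).

Internally lengths are mm and moduli/pressures Pa (a consistent pair for
a 2-D per-unit-thickness problem); stresses are reported in kPa.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (PlaqueCrossSection, angular_footprint, ray_crossings)

__all__ = [
    "MaterialProperties",
    "SimulationConfig",
    "Mesh",
    "StressField",
    "default_materials",
    "material_variants",
    "build_mesh",
    "solve_elasticity",
    "von_mises",
    "lame_annulus_reference",
    "LameAnnulus",
]

REGIONS = ("cap", "lipid", "calcification", "wall")

# mesh edge-length scale per refinement level
REFINEMENT_SCALE = {"coarse": 2.0, "fine": 1.0, "very_fine": 0.5}


@dataclass
class MaterialProperties:
    """Per-region linear-elastic constants: Young's modulus (Pa), Poisson ratio."""

    regions: Dict[str, tuple]

    def __post_init__(self) -> None:
        for name, (e, nu) in self.regions.items():
            if e <= 0:
                raise ValueError(f"{name}: Young's modulus must be positive")
            if not (0 <= nu < 0.5):
                raise ValueError(f"{name}: Poisson ratio must be in [0, 0.5)")

    def __getitem__(self, name: str) -> tuple:
        return self.regions[name]


def default_materials() -> MaterialProperties:
    """Literature-based defaults: soft necrotic core, stiff crystalline calcium."""
    return MaterialProperties({
        "cap": (244e3, 0.27),
        "lipid": (1e3, 0.48),
        "calcification": (10e9, 0.30),
        "wall": (800e3, 0.27),
    })


def material_variants(base: MaterialProperties, variant: str) -> MaterialProperties:
    """Named sensitivity variants of a material set.

    ``wall_incompressible`` sets the wall (and cap) Poisson ratio to 0.48,
    the nearly-incompressible assumption; ``soft_calcification`` lowers the
    calcification modulus to 10 MPa (mildly calcified tissue);
    ``bone_calcification`` raises it to 20 GPa (bone-like).
    """
    regions = dict(base.regions)
    if variant == "wall_incompressible":
        for name in ("wall", "cap"):
            e, _ = regions[name]
            regions[name] = (e, 0.48)
    elif variant == "soft_calcification":
        regions["calcification"] = (10e6, regions["calcification"][1])
    elif variant == "bone_calcification":
        regions["calcification"] = (20e9, regions["calcification"][1])
    else:
        raise ValueError(f"unknown material variant: {variant!r}")
    return MaterialProperties(regions)


@dataclass
class SimulationConfig:
    """Load and meshing parameters.

    ``pressure_kpa`` defaults to 17 kPa (130 mmHg).  Edge lengths are
    targets in mm (cap region vs. everything else); ``refinement`` scales
    both ('fine' = 1x, 'very_fine' = 0.5x, 'coarse' = 2x).
    """

    pressure_kpa: float = 17.0
    cap_edge_mm: float = 0.05
    wall_edge_mm: float = 0.2
    refinement: str = "fine"
    n_theta: Optional[int] = None
    inclusion_band_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.pressure_kpa < 0:
            raise ValueError("pressure must be >= 0")
        if self.cap_edge_mm <= 0 or self.wall_edge_mm <= 0:
            raise ValueError("edge lengths must be positive")
        if self.refinement not in REFINEMENT_SCALE:
            raise ValueError(f"unknown refinement level: {self.refinement!r}")

    @property
    def scale(self) -> float:
        return REFINEMENT_SCALE[self.refinement]

    def at_refinement(self, level: str) -> "SimulationConfig":
        return replace(self, refinement=level)


@dataclass
class Mesh:
    """Quadratic-triangle mesh with region labels and boundary bookkeeping."""

    nodes: np.ndarray          # (N, 2) mm
    elements: np.ndarray       # (M, 6) node ids; corners 0-2, mids 3-5
    region_id: np.ndarray      # (M,) index into region_names
    region_names: tuple
    lumen_edges: np.ndarray    # (n_theta, 3) quadratic boundary edges
    outer_nodes: np.ndarray    # node ids on the fixed outer circle
    lumen_nodes: np.ndarray    # node ids on the lumen boundary
    center: np.ndarray         # lumen centroid (angular origin)
    min_corner_angle_deg: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_regions(self) -> np.ndarray:
        return np.asarray(self.region_names)[self.region_id]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]].mean(axis=1)


@dataclass
class StressField:
    """Solution: nodal displacement (mm) and element-centroid stresses (kPa)."""

    displacement: np.ndarray   # (N, 2)
    sxx: np.ndarray
    syy: np.ndarray
    txy: np.ndarray
    szz: np.ndarray
    vm: np.ndarray


# --------------------------------------------------------------------------
# meshing

def _wrap_dist_ccw(a: float, b: float) -> float:
    return (b - a) % 360.0


def _in_arc(theta, start: float, extent: float, tol: float = 1e-9):
    return (np.asarray(theta) - start) % 360.0 <= extent + tol


def _single_radius(radii, kind: str, angle: float) -> float:
    if radii.size == 0:
        raise ValueError(f"ray at {angle:.2f} deg misses {kind} contour")
    return float(radii[-1])


def build_mesh(geometry: PlaqueCrossSection, config: SimulationConfig) -> Mesh:
    """Structured multi-region mesh of a star-shaped plaque cross-section.

    Radial bands: fibrous cap (lumen to cap-outer), an inclusion band
    (cap-outer to the inclusion outer boundary, blending to a default
    mid-wall radius away from inclusion sectors), and the outer wall.  The
    cap is resolved with at least 3 element layers across its thickness.
    """
    cap_edge = config.cap_edge_mm * config.scale
    wall_edge = config.wall_edge_mm * config.scale
    c = geometry.lumen_centroid()

    r_vert = np.linalg.norm(geometry.lumen.vertices - c, axis=1)
    r_mean = float(r_vert.mean())

    has_cap = geometry.cap_outer is not None
    inclusions = ([("lipid", k) for k in geometry.lipid_cores]
                  + [("calcification", k) for k in geometry.calcifications])
    if inclusions and not has_cap:
        raise ValueError("inclusions require a fibrous cap ring")

    inner_edge = cap_edge if has_cap else wall_edge
    if config.n_theta is not None:
        n_base = int(config.n_theta)
    else:
        floor = int(np.round(64 / config.scale))
        n_base = max(floor, int(np.ceil(2 * np.pi * r_mean / inner_edge)))
        n_base = int(4 * np.ceil(n_base / 4))
    delta = 360.0 / n_base

    # corner spokes: all inclusion sector edges, plus a uniform fill of
    # each gap at spacing <= delta (so sector boundaries are element edges)
    sectors = []
    targets = []
    for kind, cont in inclusions:
        extent, start, end = angular_footprint(cont, c)
        sectors.append({"kind": kind, "contour": cont,
                        "start": start, "extent": extent})
        targets += [start % 360.0, (start + extent) % 360.0]
    if targets:
        targets = sorted(set(targets))
        theta_corner = []
        for i, t in enumerate(targets):
            t_next = targets[(i + 1) % len(targets)]
            gap = _wrap_dist_ccw(t, t_next) or 360.0
            # cosine grading clusters spokes toward the sector edges, where
            # the shoulder stress concentration needs angular resolution
            n_fill = max(1, int(np.ceil(gap / delta)) + 2)
            u = np.arange(n_fill) / n_fill
            u = u - 0.5 / (2 * np.pi) * np.sin(2 * np.pi * u)
            theta_corner.extend((t + gap * u) % 360.0)
        theta_corner = np.sort(np.asarray(theta_corner))
        if np.any(np.diff(theta_corner) < 0.05 * delta):
            raise ValueError("inclusion sector edges too close together "
                             "for the angular grid")
    else:
        theta_corner = np.arange(n_base) * delta
    n_theta = theta_corner.size

    # fine angular grid: corners at even indices, midpoints at odd
    nxt = np.roll(theta_corner, -1)
    nxt[-1] += 360.0
    theta_fine = np.empty(2 * n_theta)
    theta_fine[0::2] = theta_corner
    theta_fine[1::2] = 0.5 * (theta_corner + nxt) % 360.0
    nf = theta_fine.size

    # radial breakpoints per fine angle
    r_lum = np.array([_single_radius(r, "lumen", a) for r, a in
                      zip(ray_crossings(c, theta_fine, geometry.lumen),
                          theta_fine)])
    r_out = np.array([_single_radius(r, "outer wall", a) for r, a in
                      zip(ray_crossings(c, theta_fine, geometry.outer_wall),
                          theta_fine)])
    if has_cap:
        r_cap = np.array([_single_radius(r, "cap outer", a) for r, a in
                          zip(ray_crossings(c, theta_fine, geometry.cap_outer),
                              theta_fine)])
        if np.any(r_cap <= r_lum + 1e-9):
            raise ValueError("degenerate region: zero-width fibrous cap")
    else:
        r_cap = r_lum
    if np.any(r_out <= r_cap + 1e-9):
        raise ValueError("degenerate region: cap reaches the outer wall")

    # inclusion band outer boundary R_A(theta): inclusion exit radius inside
    # each sector, cosine-blended to a default mid-wall radius outside
    wall_thick = r_out - r_cap
    if inclusions:
        default_ra = r_cap + config.inclusion_band_fraction * wall_thick
        dev = np.zeros(nf)
        touched = np.zeros(nf, dtype=int)
        ramp_w = max(10.0, 3.0 * delta)
        for sec in sectors:
            start, extent = sec["start"], sec["extent"]
            crossings = ray_crossings(c, theta_fine, sec["contour"])
            inside = _in_arc(theta_fine, start, extent, tol=1e-7)
            edge_margin = 0.75 * delta   # skip grazing rays at sector edges
            exit_r = np.full(nf, np.nan)
            for i in np.nonzero(inside)[0]:
                hits = crossings[i]
                if hits.size:
                    exit_r[i] = hits[-1]
                    interior = min(_wrap_dist_ccw(start, theta_fine[i]),
                                   _wrap_dist_ccw(theta_fine[i],
                                                  (start + extent) % 360.0)
                                   ) > edge_margin
                    if interior and hits[0] > r_cap[i] + 0.08 * wall_thick[i]:
                        raise ValueError(
                            f"{sec['kind']} inclusion not adjacent to the cap "
                            f"at {theta_fine[i]:.1f} deg (unsupported geometry)")
            # fill grazing rays at sector edges from neighbours; near the
            # edges an "exit" indistinguishable from the entry is also a
            # grazing artefact (square-ended sectors), while shallow exits
            # in the sector interior are genuine (tapered lens cores)
            idx = np.nonzero(inside)[0]
            if idx.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med_depth = np.nanmedian(exit_r[idx] - r_cap[idx])
            if np.isfinite(med_depth) and med_depth > 0:
                near_edge = np.minimum(
                    _wrap_dist_ccw(start, theta_fine[idx]),
                    _wrap_dist_ccw(theta_fine[idx],
                                   (start + extent) % 360.0)) <= 2 * edge_margin
                shallow = exit_r[idx] < r_cap[idx] + 0.3 * med_depth
                exit_r[idx[shallow & near_edge]] = np.nan
            good = idx[~np.isnan(exit_r[idx])]
            if good.size == 0:
                continue
            for i in idx[np.isnan(exit_r[idx])]:
                j = good[np.argmin(np.abs(good - i))]
                exit_r[i] = exit_r[j]
            d_here = np.zeros(nf)
            d_here[idx] = exit_r[idx] - default_ra[idx]
            # cosine ramps outside the sector, anchored at the edge values
            end = (start + extent) % 360.0
            off_start = _wrap_dist_ccw(theta_fine[idx], start)
            off_start[off_start > 180] -= 360.0
            exit_at_start = exit_r[idx[np.argmin(np.abs(off_start))]]
            off_end = _wrap_dist_ccw(end, theta_fine[idx])
            off_end[off_end > 180] -= 360.0
            exit_at_end = exit_r[idx[np.argmin(np.abs(off_end))]]
            influence = inside.copy()
            for i in np.nonzero(~inside)[0]:
                d_after = _wrap_dist_ccw(end, theta_fine[i])
                d_before = _wrap_dist_ccw(theta_fine[i], start)
                ramp = 0.0
                if d_after < ramp_w:
                    ramp += (exit_at_end - default_ra[i]) \
                        * 0.5 * (1 + np.cos(np.pi * d_after / ramp_w))
                if d_before < ramp_w:
                    ramp += (exit_at_start - default_ra[i]) \
                        * 0.5 * (1 + np.cos(np.pi * d_before / ramp_w))
                if ramp != 0.0:
                    d_here[i] = ramp
                    influence[i] = True
            touched += influence.astype(int)
            dev += d_here
        if np.any(touched > 1):
            raise ValueError("inclusion sectors too close together for the "
                             "banded mesher (overlapping blend windows)")
        r_band = np.clip(default_ra + dev,
                         r_cap + 0.02 * wall_thick,
                         r_out - 0.02 * wall_thick)
    else:
        r_band = None

    # band list: (inner radii, outer radii, layer count, kind)
    bands = []
    if has_cap:
        # radial cap resolution 5x finer than the tangential target: the
        # peak cap stress is read at element centroids, so its mesh
        # stability is governed by the innermost-layer thickness
        n_cap_layers = max(3, int(np.round(np.median(r_cap - r_lum)
                                           / (0.2 * cap_edge))))
        bands.append((r_lum, r_cap, n_cap_layers, "cap"))
        if r_band is not None:
            n_a = max(2, int(np.round(np.median(r_band - r_cap) / wall_edge)))
            bands.append((r_cap, r_band, n_a, "band"))
            n_w = max(2, int(np.round(np.median(r_out - r_band) / wall_edge)))
            bands.append((r_band, r_out, n_w, "wall"))
        else:
            n_w = max(3, int(np.round(np.median(r_out - r_cap) / wall_edge)))
            bands.append((r_cap, r_out, n_w, "wall"))
    else:
        n_w = max(3, int(np.round(np.median(r_out - r_lum) / wall_edge)))
        bands.append((r_lum, r_out, n_w, "wall"))

    # fine ring radii (2*layers per band, shared band boundaries)
    ring_r = [bands[0][0]]
    band_kind_per_layer = []
    for (ri, ro, nlay, kind) in bands:
        for s in range(1, 2 * nlay + 1):
            ring_r.append(ri + (ro - ri) * (s / (2 * nlay)))
        band_kind_per_layer += [kind] * nlay
    ring_r = np.array(ring_r)                       # (2L+1, nf)
    n_layers = len(band_kind_per_layer)

    # nodes
    cth = np.cos(np.radians(theta_fine))
    sth = np.sin(np.radians(theta_fine))
    nodes = np.empty((ring_r.shape[0] * nf, 2))
    for i in range(ring_r.shape[0]):
        nodes[i * nf:(i + 1) * nf, 0] = c[0] + ring_r[i] * cth
        nodes[i * nf:(i + 1) * nf, 1] = c[1] + ring_r[i] * sth

    def nid(i, j):
        return i * nf + (j % nf)

    # straight-sided quadratic elements: snap mid-edge nodes to chord
    # midpoints (radial, arc and diagonal edges).  Keeps the isoparametric
    # map affine, so element validity follows from ring monotonicity; the
    # O(h^2) boundary-chord error matches the discretization order.
    n_rings = ring_r.shape[0]
    even_i = np.arange(0, n_rings, 2)
    odd_i = np.arange(1, n_rings, 2)
    even_j = np.arange(0, nf, 2)
    odd_j = np.arange(1, nf, 2)
    # radial mids (odd i, even j)
    for i in odd_i:
        nodes[i * nf + even_j] = 0.5 * (nodes[(i - 1) * nf + even_j]
                                        + nodes[(i + 1) * nf + even_j])
    # arc mids (even i, odd j)
    for i in even_i:
        nodes[i * nf + odd_j] = 0.5 * (nodes[i * nf + (odd_j - 1)]
                                       + nodes[i * nf + (odd_j + 1) % nf])
    # diagonal mids (odd i, odd j): edge (i-1, j-1) -> (i+1, j+1)
    for i in odd_i:
        nodes[i * nf + odd_j] = 0.5 * (nodes[(i - 1) * nf + (odd_j - 1)]
                                       + nodes[(i + 1) * nf + (odd_j + 1) % nf])

    # per-column region for the inclusion band
    col_region = np.full(n_theta, REGIONS.index("wall"), dtype=np.int8)
    if inclusions:
        mid_angles = theta_fine[1::2]
        for sec in sectors:
            hit = _in_arc(mid_angles, sec["start"], sec["extent"], tol=-1e-7)
            col_region[hit] = REGIONS.index(sec["kind"])

    elements = []
    region_id = []
    for layer in range(n_layers):
        kind = band_kind_per_layer[layer]
        i0 = 2 * layer
        for col in range(n_theta):
            j0 = 2 * col
            if kind == "cap":
                reg = REGIONS.index("cap")
            elif kind == "wall":
                reg = REGIONS.index("wall")
            else:
                reg = col_region[col]
            # lower-left triangle: radial edge, outer arc corner
            elements.append([nid(i0, j0), nid(i0 + 2, j0), nid(i0 + 2, j0 + 2),
                             nid(i0 + 1, j0), nid(i0 + 2, j0 + 1),
                             nid(i0 + 1, j0 + 1)])
            # upper-right triangle
            elements.append([nid(i0, j0), nid(i0 + 2, j0 + 2), nid(i0, j0 + 2),
                             nid(i0 + 1, j0 + 1), nid(i0 + 1, j0 + 2),
                             nid(i0, j0 + 1)])
            region_id += [reg, reg]
    elements = np.asarray(elements, dtype=np.int64)
    region_id = np.asarray(region_id, dtype=np.int8)

    lumen_edges = np.array([[nid(0, 2 * j), nid(0, 2 * j + 1),
                             nid(0, 2 * j + 2)] for j in range(n_theta)],
                           dtype=np.int64)
    outer_nodes = np.arange((ring_r.shape[0] - 1) * nf, ring_r.shape[0] * nf)
    lumen_nodes = np.arange(nf)

    # corner-triangle quality
    tri = nodes[elements[:, :3]]
    angs = []
    for k in range(3):
        a = tri[:, (k + 1) % 3] - tri[:, k]
        b = tri[:, (k + 2) % 3] - tri[:, k]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    min_angle = float(np.min(angs))

    return Mesh(nodes=nodes, elements=elements, region_id=region_id,
                region_names=REGIONS, lumen_edges=lumen_edges,
                outer_nodes=outer_nodes, lumen_nodes=lumen_nodes,
                center=c, min_corner_angle_deg=min_angle)


# --------------------------------------------------------------------------
# quadratic triangle reference element

def _shape_grad(xi: float, eta: float):
    l1, l2, l3 = 1.0 - xi - eta, xi, eta
    n = np.array([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                  4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1])
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    dn = np.vstack([
        (4 * l1 - 1) * dl[0],
        (4 * l2 - 1) * dl[1],
        (4 * l3 - 1) * dl[2],
        4 * (l2 * dl[0] + l1 * dl[1]),
        4 * (l3 * dl[1] + l2 * dl[2]),
        4 * (l1 * dl[2] + l3 * dl[0]),
    ])
    return n, dn                                    # (6,), (6,2)


# 6-point degree-4 rule on the unit reference triangle
_GA = 0.445948490915965
_GB = 0.091576213509771
_GPOINTS = [(_GA, _GA), (1 - 2 * _GA, _GA), (_GA, 1 - 2 * _GA),
            (_GB, _GB), (1 - 2 * _GB, _GB), (_GB, 1 - 2 * _GB)]
_GWEIGHTS = [0.223381589678011 / 2] * 3 + [0.109951743655322 / 2] * 3


def _plane_strain_d(e: float, nu: float) -> np.ndarray:
    f = e / ((1 + nu) * (1 - 2 * nu))
    return f * np.array([[1 - nu, nu, 0.0],
                         [nu, 1 - nu, 0.0],
                         [0.0, 0.0, (1 - 2 * nu) / 2]])


def solve_elasticity(mesh: Mesh, materials: MaterialProperties,
                     config: SimulationConfig) -> StressField:
    """Assemble and solve the plane-strain problem; recover centroid stresses.

    Pressure acts as a traction -p n on the undeformed lumen boundary
    (pushing the wall outward); the outer circle is fully fixed.  The
    symmetric system is solved with a direct sparse factorization (the
    modulus contrast between lipid and calcification spans seven orders
    of magnitude, which iterative solvers tolerate poorly).
    """
    nodes, elements = mesh.nodes, mesh.elements
    nel = mesh.n_elements
    present = np.unique(mesh.region_id)
    dmats = {}
    nus = {}
    for rid in present:
        name = mesh.region_names[rid]
        if name not in materials.regions:
            raise ValueError(f"no material for region {name!r}")
        e, nu = materials[name]
        dmats[rid] = _plane_strain_d(e, nu)
        nus[rid] = nu
    d_el = np.stack([dmats[rid] for rid in mesh.region_id])     # (M,3,3)

    coords = nodes[elements]                                    # (M,6,2)
    ke = np.zeros((nel, 12, 12))
    ix = np.arange(6)
    for (xi, eta), w in zip(_GPOINTS, _GWEIGHTS):
        _, dn = _shape_grad(xi, eta)                            # (6,2)
        jac = np.einsum("na,mnb->mab", dn, coords)              # (M,2,2)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        if np.any(det <= 0):
            raise ValueError("non-positive Jacobian in mesh")
        inv = np.empty_like(jac)
        inv[:, 0, 0] = jac[:, 1, 1]
        inv[:, 1, 1] = jac[:, 0, 0]
        inv[:, 0, 1] = -jac[:, 0, 1]
        inv[:, 1, 0] = -jac[:, 1, 0]
        inv /= det[:, None, None]
        grad = np.einsum("na,mba->mnb", dn, inv)                # (M,6,2)
        b = np.zeros((nel, 3, 12))
        b[:, 0, 2 * ix] = grad[:, :, 0]
        b[:, 1, 2 * ix + 1] = grad[:, :, 1]
        b[:, 2, 2 * ix] = grad[:, :, 1]
        b[:, 2, 2 * ix + 1] = grad[:, :, 0]
        db = np.einsum("mij,mjk->mik", d_el, b)
        ke += (w * det)[:, None, None] * np.einsum("mji,mjk->mik", b, db)

    edof = np.empty((nel, 12), dtype=np.int64)
    edof[:, 0::2] = 2 * elements
    edof[:, 1::2] = 2 * elements + 1
    rows = np.repeat(edof, 12, axis=1).ravel()
    cols = np.tile(edof, (1, 12)).ravel()
    ndof = 2 * mesh.n_nodes
    kmat = sp.coo_matrix((ke.ravel(), (rows, cols)),
                         shape=(ndof, ndof)).tocsr()

    # consistent pressure load on the quadratic lumen edges
    f = np.zeros(ndof)
    p_pa = config.pressure_kpa * 1e3
    if p_pa != 0.0:
        gauss_1d = [(-np.sqrt(3 / 5), 5 / 9), (0.0, 8 / 9),
                    (np.sqrt(3 / 5), 5 / 9)]
        ex = nodes[mesh.lumen_edges]                            # (ne,3,2)
        for xi, w in gauss_1d:
            nsh = np.array([xi * (xi - 1) / 2, 1 - xi * xi, xi * (xi + 1) / 2])
            dsh = np.array([xi - 0.5, -2 * xi, xi + 0.5])
            tang = np.einsum("a,eab->eb", dsh, ex)              # (ne,2)
            normal = np.column_stack([tang[:, 1], -tang[:, 0]])
            mid = np.einsum("a,eab->eb", nsh, ex)
            sgn = np.sign(np.einsum("eb,eb->e", normal,
                                    mid - mesh.center[None, :]))
            trac = p_pa * sgn[:, None] * normal                 # includes |J|
            for a in range(3):
                np.add.at(f, 2 * mesh.lumen_edges[:, a], w * nsh[a] * trac[:, 0])
                np.add.at(f, 2 * mesh.lumen_edges[:, a] + 1, w * nsh[a] * trac[:, 1])

    fixed = np.zeros(ndof, dtype=bool)
    fixed[2 * mesh.outer_nodes] = True
    fixed[2 * mesh.outer_nodes + 1] = True
    free = ~fixed
    if not np.any(fixed):
        raise ValueError("no Dirichlet constraints; system is singular")

    u = np.zeros(ndof)
    if p_pa != 0.0:
        kff = kmat[free][:, free]
        sol = spla.spsolve(kff.tocsc(), f[free])
        if not np.all(np.isfinite(sol)):
            es = [materials[mesh.region_names[r]][0] for r in present]
            raise ValueError("non-finite solution; stiffness ratio "
                             f"{max(es) / min(es):.1e} too extreme")
        u[free] = sol

    # centroid stress recovery
    _, dn = _shape_grad(1 / 3, 1 / 3)
    jac = np.einsum("na,mnb->mab", dn, coords)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    grad = np.einsum("na,mba->mnb", dn, inv)
    b = np.zeros((nel, 3, 12))
    b[:, 0, 2 * ix] = grad[:, :, 0]
    b[:, 1, 2 * ix + 1] = grad[:, :, 1]
    b[:, 2, 2 * ix] = grad[:, :, 1]
    b[:, 2, 2 * ix + 1] = grad[:, :, 0]
    ue = u[edof]
    sig = np.einsum("mij,mjk,mk->mi", d_el, b, ue)              # Pa
    nu_el = np.array([nus[rid] for rid in mesh.region_id])
    szz = nu_el * (sig[:, 0] + sig[:, 1])
    vm = von_mises(sig[:, 0], sig[:, 1], szz, sig[:, 2])

    scale = 1e-3  # Pa -> kPa
    return StressField(displacement=u.reshape(-1, 2),
                       sxx=sig[:, 0] * scale, syy=sig[:, 1] * scale,
                       txy=sig[:, 2] * scale, szz=szz * scale,
                       vm=vm * scale)


def von_mises(sxx, syy, szz, txy):
    """Equivalent (von Mises) stress from in-plane + out-of-plane components."""
    sxx, syy, szz, txy = (np.asarray(v, float) for v in (sxx, syy, szz, txy))
    val = (sxx ** 2 + syy ** 2 + szz ** 2
           - sxx * syy - syy * szz - szz * sxx + 3 * txy ** 2)
    return np.sqrt(np.maximum(val, 0.0))


# --------------------------------------------------------------------------
# analytic oracle: pressurized annulus with fixed outer edge

@dataclass
class LameAnnulus:
    """Closed-form plane-strain solution u(r) = A r + B / r.

    Boundary conditions: sigma_rr(a) = -p (internal pressure) and
    u(b) = 0 (fixed outer edge).  Radii in mm, stresses in kPa.
    """

    a: float
    b: float
    e_pa: float
    nu: float
    p_kpa: float
    coef_a: float = field(init=False)
    coef_b: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.a < self.b:
            raise ValueError("need 0 < a < b")
        lam = self.e_pa * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.e_pa / (2 * (1 + self.nu))
        p = self.p_kpa * 1e3
        # sigma_rr = 2(lam+mu)A - 2 mu B / r^2 ; u(b)=0 -> B = -A b^2
        self.coef_a = -p / (2 * (lam + mu) + 2 * mu * self.b ** 2 / self.a ** 2)
        self.coef_b = -self.coef_a * self.b ** 2
        self._lam, self._mu = lam, mu

    def u(self, r):
        r = np.asarray(r, float)
        return self.coef_a * r + self.coef_b / r

    def sigma_rr(self, r):
        r = np.asarray(r, float)
        val = (2 * (self._lam + self._mu) * self.coef_a
               - 2 * self._mu * self.coef_b / r ** 2)
        return val * 1e-3

    def sigma_theta(self, r):
        r = np.asarray(r, float)
        val = (2 * (self._lam + self._mu) * self.coef_a
               + 2 * self._mu * self.coef_b / r ** 2)
        return val * 1e-3

    def sigma_zz(self, r):
        return self.nu * (self.sigma_rr(r) + self.sigma_theta(r))

    def von_mises(self, r):
        return von_mises(self.sigma_rr(r), self.sigma_theta(r),
                         self.sigma_zz(r), 0.0)


def lame_annulus_reference(a: float, b: float, e_pa: float, nu: float,
                           p_kpa: float) -> LameAnnulus:
    """Analytic pressurized-annulus reference for solver verification."""
    return LameAnnulus(a=a, b=b, e_pa=e_pa, nu=nu, p_kpa=p_kpa)
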