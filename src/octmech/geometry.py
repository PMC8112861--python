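"""Geometric model of a multi-material coronary plaque cross-section.

A lesion slice is described by closed planar contours (in mm): the lumen
boundary, the outer vessel wall (a 4 mm diameter circle by convention), the
outer boundary of the fibrous cap, and zero or more lipid-core and
calcification contours embedded in the wall.  All angular quantities are
measured about the lumen centroid, in degrees, counter-clockwise, with 0 at
the +x axis — the angular frame used for per-frame OCT morphometry.

Fibrous cap thickness (FCT) is measured radially from the lumen centroid:
for each ray, the thickness is the distance from the lumen boundary to the
first non-cap material (lipid, calcification, or plain wall).  This is an
approximation to a surface-normal measurement, chosen because it is simple,
reproducible and matches the angular convention of clinical OCT analysis.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "Contour",
    "PlaqueCrossSection",
    "LesionMorphology",
    "circle_contour",
    "validate_cross_section",
    "cap_thickness_profile",
    "lipid_arc",
    "lumen_area",
    "angular_position",
    "ray_crossings",
    "angular_footprint",
    "lesion_to_json",
    "lesion_from_json",
    "contours_from_csv",
]


@dataclass
class Contour:
    """A closed, simple polygon stored as an (n, 2) vertex array in mm.

    The first vertex is not repeated; closure is implicit.  Vertices are
    normalized to counter-clockwise orientation on construction.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("contour vertices must be an (n, 2) array")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] >= 3 and _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    def area(self) -> float:
        return abs(self.signed_area())

    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon().centroid.coords[0], dtype=float)

    def is_simple(self) -> bool:
        if self.n < 3:
            return False
        return self.polygon().is_valid

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def transformed(self, rotation_deg: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0)) -> "Contour":
        a = np.radians(rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return Contour(self.vertices @ rot.T + np.asarray(translation, float))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def circle_contour(radius: float, center: Sequence[float] = (0.0, 0.0),
                   n: int = 256) -> Contour:
    """Regular n-gon approximation of a circle (CCW)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    c = np.asarray(center, float)
    return Contour(np.column_stack([c[0] + radius * np.cos(t),
                                    c[1] + radius * np.sin(t)]))


@dataclass
class PlaqueCrossSection:
    """Region-labelled cross-section of one lesion.

    ``cap_outer`` bounds the fibrous cap ring (between the lumen and
    ``cap_outer``); it may be ``None`` for homogeneous test geometries, in
    which case the whole annulus is vessel wall.  Lipid cores and
    calcifications live between ``cap_outer`` and ``outer_wall``.
    """

    lumen: Contour
    outer_wall: Contour
    cap_outer: Optional[Contour] = None
    lipid_cores: list = field(default_factory=list)
    calcifications: list = field(default_factory=list)

    def lumen_centroid(self) -> np.ndarray:
        return self.lumen.centroid()

    def all_contours(self):
        out = [("lumen", self.lumen), ("outer_wall", self.outer_wall)]
        if self.cap_outer is not None:
            out.append(("cap_outer", self.cap_outer))
        out += [(f"lipid[{i}]", c) for i, c in enumerate(self.lipid_cores)]
        out += [(f"calcification[{i}]", c)
                for i, c in enumerate(self.calcifications)]
        return out

    def transformed(self, rotation_deg: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0)) -> "PlaqueCrossSection":
        t = lambda c: c.transformed(rotation_deg, translation)
        return PlaqueCrossSection(
            lumen=t(self.lumen),
            outer_wall=t(self.outer_wall),
            cap_outer=None if self.cap_outer is None else t(self.cap_outer),
            lipid_cores=[t(c) for c in self.lipid_cores],
            calcifications=[t(c) for c in self.calcifications],
        )


@dataclass
class LesionMorphology:
    """Per-lesion OCT morphology annotations.

    Units: FCT in micrometres, arcs in degrees, lengths in mm, MLA in mm^2.
    ``rupture_angle`` is present exactly when ``ruptured`` is true.
    """

    min_fct: float
    mean_fct: float
    max_lipid_arc: float
    mean_lipid_arc: float
    lipid_length: float
    mla: float
    macrophages_present: bool
    ruptured: bool
    macrophage_arc: float = 0.0
    macrophage_length: float = 0.0
    spotty_calcification: bool = False
    rupture_angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ruptured and self.rupture_angle is None:
            raise ValueError("ruptured lesion requires a rupture_angle")
        if not self.ruptured and self.rupture_angle is not None:
            raise ValueError("rupture_angle given for a non-ruptured lesion")


# --------------------------------------------------------------------------
# ray casting

def ray_crossings(center: np.ndarray, angles_deg: np.ndarray,
                  contour: Contour) -> list:
    """Radii at which rays from ``center`` cross the contour boundary.

    Returns one sorted array of positive radii per angle.  Vectorized over
    (edges x rays); collinear edge/ray pairs are ignored.
    """
    c = np.asarray(center, float)
    ang = np.radians(np.atleast_1d(np.asarray(angles_deg, float)))
    d = np.column_stack([np.cos(ang), np.sin(ang)])          # (m,2)
    a = contour.vertices                                      # (n,2)
    b = np.roll(a, -1, axis=0)
    e = b - a                                                 # (n,2)
    w = a - c                                                 # (n,2)
    # t = (w x e)/(d x e), s = (w x d)/(d x e), crossing if 0<=s<1, t>0
    dxe = d[:, 0][:, None] * e[:, 1][None, :] - d[:, 1][:, None] * e[:, 0][None, :]
    wxe = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]               # (n,)
    wxd = w[None, :, 0] * d[:, 1][:, None] - w[None, :, 1] * d[:, 0][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxe[None, :] / dxe
        s = wxd / dxe
    # small tolerance at s=0 so rays through a polygon vertex register on
    # the outgoing edge (the incoming edge is excluded at s=1)
    ok = (np.abs(dxe) > 1e-14) & (s >= -1e-9) & (s < 1.0 - 1e-9) & (t > 1e-12)
    return [np.sort(t[i][ok[i]]) for i in range(ang.size)]


def angular_footprint(contour: Contour, center: np.ndarray):
    """Angular extent (deg) of a contour seen from ``center``.

    Returns ``(extent_deg, start_deg, end_deg)`` with the arc running CCW
    from start to end.  Computed as 360 minus the largest angular gap
    between boundary vertices, which is exact for contours that do not
    enclose the center.
    """
    v = contour.vertices - np.asarray(center, float)
    ang = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360.0
    ang = np.sort(ang)
    gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
    i = int(np.argmax(gaps))
    extent = 360.0 - gaps[i]
    start = ang[(i + 1) % ang.size]
    end = ang[i]
    return float(extent), float(start), float(end)


# --------------------------------------------------------------------------
# operations

def validate_cross_section(geometry: PlaqueCrossSection) -> list:
    """Check all cross-section invariants; return a list of violations.

    An empty list means the geometry is valid.  Violations name the
    offending contour and rule; nothing is raised.
    """
    out: list = []
    named = geometry.all_contours()
    polys = {}
    for name, c in named:
        if c.n < 3:
            out.append(f"{name} has fewer than 3 vertices")
            continue
        if not c.is_simple():
            out.append(f"{name} not simple")
            continue
        if c.area() <= 0:
            out.append(f"{name} has non-positive area")
            continue
        polys[name] = c.polygon()
    if "lumen" not in polys or "outer_wall" not in polys:
        return out
    lum, wall = polys["lumen"], polys["outer_wall"]
    if not wall.contains(lum):
        out.append("lumen outside wall")
    if "cap_outer" in polys:
        cap = polys["cap_outer"]
        if not cap.contains(lum):
            out.append("cap_outer does not enclose lumen")
        if not wall.contains(cap):
            out.append("cap_outer outside wall")
    inclusions = [(n, p) for n, p in polys.items()
                  if n.startswith("lipid") or n.startswith("calcification")]
    for n, p in inclusions:
        if not wall.contains(p):
            out.append(f"{n} outside wall")
        if p.intersection(lum).area > 1e-9:
            out.append(f"{n} overlaps lumen")
    for i in range(len(inclusions)):
        for j in range(i + 1, len(inclusions)):
            ni, pi = inclusions[i]
            nj, pj = inclusions[j]
            if pi.intersection(pj).area > 1e-9:
                out.append(f"{ni} overlaps {nj}")
    return out


def cap_thickness_profile(geometry: PlaqueCrossSection,
                          n_rays: int = 360) -> np.ndarray:
    """Radial fibrous-cap thickness profile about the lumen centroid.

    Returns an (n_rays, 2) array of ``(angle_deg, thickness_um)``.  For each
    ray the thickness runs from the lumen boundary to the first non-cap
    material crossed: a lipid core, a calcification, or (at the cap outer
    boundary) the plain vessel wall.
    """
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8")
    if geometry.cap_outer is None:
        raise ValueError("geometry has no fibrous cap ring")
    c = geometry.lumen_centroid()
    ang = np.arange(n_rays) * (360.0 / n_rays)
    r_lum = ray_crossings(c, ang, geometry.lumen)
    r_cap = ray_crossings(c, ang, geometry.cap_outer)
    incl = [ray_crossings(c, ang, k)
            for k in geometry.lipid_cores + geometry.calcifications]
    thick = np.empty(n_rays)
    for i in range(n_rays):
        if r_lum[i].size == 0 or r_cap[i].size == 0:
            raise ValueError(f"ray at {ang[i]:.1f} deg misses lumen or cap boundary")
        r0 = r_lum[i][-1]
        stop = r_cap[i][r_cap[i] > r0 + 1e-12]
        if stop.size == 0:
            raise ValueError(f"cap boundary not outside lumen at {ang[i]:.1f} deg")
        first = stop[0]
        for radii in incl:
            hits = radii[i][radii[i] > r0 + 1e-12]
            if hits.size:
                first = min(first, hits[0])
        thick[i] = (first - r0) * 1000.0  # mm -> um
    return np.column_stack([ang, thick])


def lipid_arc(geometry: PlaqueCrossSection):
    """Maximal lipid-core arc (deg) and per-core arcs about the lumen centroid."""
    c = geometry.lumen_centroid()
    arcs = [angular_footprint(k, c)[0] for k in geometry.lipid_cores]
    return (max(arcs) if arcs else 0.0), arcs


def lumen_area(geometry: PlaqueCrossSection) -> float:
    """Lumen cross-sectional area in mm^2 (shoelace formula)."""
    return geometry.lumen.area()


def angular_position(point: Sequence[float],
                     geometry: PlaqueCrossSection) -> float:
    """Angle of a point about the lumen centroid, degrees in [0, 360)."""
    c = geometry.lumen_centroid()
    v = np.asarray(point, float) - c
    r = float(np.hypot(v[0], v[1]))
    if r < 1e-12:
        raise ValueError("point coincides with the lumen centroid")
    return float(np.degrees(np.arctan2(v[1], v[0])) % 360.0)


# --------------------------------------------------------------------------
# serialization

def _morph_to_dict(m: LesionMorphology) -> dict:
    return asdict(m)


def lesion_to_json(geometry: PlaqueCrossSection,
                   morphology: Optional[LesionMorphology] = None,
                   lesion_id: str = "lesion") -> str:
    doc = {
        "id": lesion_id,
        "units": "mm",
        "regions": {
            "lumen": geometry.lumen.vertices.tolist(),
            "outer_wall": geometry.outer_wall.vertices.tolist(),
            "cap_outer": (None if geometry.cap_outer is None
                          else geometry.cap_outer.vertices.tolist()),
            "lipid": [c.vertices.tolist() for c in geometry.lipid_cores],
            "calcification": [c.vertices.tolist()
                              for c in geometry.calcifications],
        },
        "morphology": None if morphology is None else _morph_to_dict(morphology),
    }
    return json.dumps(doc)


def lesion_from_json(text: str):
    doc = json.loads(text)
    reg = doc["regions"]
    geom = PlaqueCrossSection(
        lumen=Contour(np.asarray(reg["lumen"], float)),
        outer_wall=Contour(np.asarray(reg["outer_wall"], float)),
        cap_outer=(None if reg.get("cap_outer") is None
                   else Contour(np.asarray(reg["cap_outer"], float))),
        lipid_cores=[Contour(np.asarray(v, float)) for v in reg.get("lipid", [])],
        calcifications=[Contour(np.asarray(v, float))
                        for v in reg.get("calcification", [])],
    )
    morph = doc.get("morphology")
    morphology = None if morph is None else LesionMorphology(**morph)
    return doc.get("id", "lesion"), geom, morphology


def contours_from_csv(path) -> PlaqueCrossSection:
    """Read a flat contour CSV (columns: region, ring_index, x_mm, y_mm)."""
    rows: dict = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (rec["region"], int(rec["ring_index"]))
            rows.setdefault(key, []).append([float(rec["x_mm"]),
                                             float(rec["y_mm"])])
    def grab(region):
        ks = sorted(k for k in rows if k[0] == region)
        return [Contour(np.asarray(rows[k], float)) for k in ks]
    lumen = grab("lumen")
    wall = grab("outer_wall")
    if not lumen or not wall:
        raise ValueError("CSV must contain lumen and outer_wall contours")
    cap = grab("cap_outer")
    return PlaqueCrossSection(
        lumen=lumen[0], outer_wall=wall[0],
        cap_outer=cap[0] if cap else None,
        lipid_cores=grab("lipid"), calcifications=grab("calcification"))
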