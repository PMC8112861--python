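"""Synthetic two-group lesion cohort emulating the study populations.

Patient OCT pullbacks were not deposited, so downstream stages are
exercised on synthetic cross-sections drawn from the published group
morphology summaries: a *stable* (non-ruptured) population with thick caps
and small lipid arcs, and a *vulnerable* (ruptured-like) population with
thin caps and large arcs.  Continuous morphology is sampled from truncated
normals at physiologic bounds (FCT >= 20 um, lipid arc in [30, 360] deg);
binary features are Bernoulli.  Each lesion gets its own random substream
spawned from the master seed, so cohorts are reproducible and lesions
independent.

Geometry construction: the lumen is a smoothly perturbed circle inside a
4 mm diameter vessel; the fibrous cap is a ring whose thickness profile is
cosine-tapered from a group-level maximum down to the sampled minimal FCT
at the centre of the lipid sector (a C1 profile, avoiding artificial
stress singularities); the necrotic core is an annular sector attached to
the outer side of the cap; an optional calcification sector sits away from
the lipid sector.  The ground-truth rupture angle of a vulnerable lesion
is the realized minimal-FCT angle plus wrapped-normal noise (default sd
20 deg, on the scale of the angular scatter reported between rupture sites
and stress maxima in patients).  Morphology annotations are measured from
the realized polygons, not copied from the sampled targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import (Contour, LesionMorphology, PlaqueCrossSection,
                       cap_thickness_profile, circle_contour, lipid_arc,
                       lumen_area, lesion_to_json, validate_cross_section)

__all__ = ["GroupParams", "CohortConfig", "Lesion",
           "generate_lesion", "generate_cohort", "perturb_contours",
           "write_cohort"]

OUTER_RADIUS_MM = 2.0          # vessel external diameter 4 mm
GROUPS = ("stable", "vulnerable")


@dataclass
class GroupParams:
    """Morphology distribution of one lesion population (mean, sd pairs)."""

    min_fct_um: tuple
    cap_max_um: tuple
    max_lipid_arc_deg: tuple
    lipid_length_mm: tuple
    lipid_depth_mm: tuple = (0.4, 0.1)
    lumen_radius_mm: tuple = (1.0, 0.12)
    macrophage_prob: float = 0.5
    spotty_calc_prob: float = 0.75
    macrophage_arc_deg: tuple = (60.0, 20.0)
    macrophage_length_mm: tuple = (5.0, 2.0)


def _default_groups() -> dict:
    # group summaries of the two patient populations: stable 97+/-15 um min
    # FCT and 110+/-8 deg arc; vulnerable 49+/-10 um and 178+/-39 deg.
    # Lipid lengths are chosen so arc x length matches the reported
    # lipid-volume-index group means; cap_max values place the realized
    # mean FCT at the reported 133 / 94 um under the cosine taper.
    return {
        "stable": GroupParams(min_fct_um=(97.0, 15.0), cap_max_um=(140.0, 12.0),
                              max_lipid_arc_deg=(110.0, 8.0),
                              lipid_length_mm=(35.0, 10.0),
                              macrophage_prob=0.4, spotty_calc_prob=0.7),
        "vulnerable": GroupParams(min_fct_um=(49.0, 10.0), cap_max_um=(105.0, 15.0),
                                  max_lipid_arc_deg=(178.0, 39.0),
                                  lipid_length_mm=(55.0, 15.0),
                                  macrophage_prob=0.6, spotty_calc_prob=0.8),
    }


@dataclass
class CohortConfig:
    """Cohort size, seed and per-group morphology distributions."""

    n_per_group: int = 10
    seed: int = 0
    groups: dict = field(default_factory=_default_groups)
    rupture_angle_noise_sd: float = 20.0
    lumen_waviness: float = 0.03
    contour_points: int = 256

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.rupture_angle_noise_sd < 0:
            raise ValueError("rupture_angle_noise_sd must be >= 0")
        for g, p in self.groups.items():
            for name in ("macrophage_prob", "spotty_calc_prob"):
                v = getattr(p, name)
                if not 0 <= v <= 1:
                    raise ValueError(f"{g}.{name} must be in [0, 1]")


@dataclass
class Lesion:
    """One generated lesion: id, group label, geometry and morphology."""

    lesion_id: str
    group: str
    geometry: PlaqueCrossSection
    morphology: LesionMorphology


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _end_rounding(arc_deg: float, n: int, round_deg: float = 10.0):
    """Depth profile over a sector: 1 in the interior, cosine-rounded to 0
    over ``round_deg`` (at most a third of the arc) at each angular end."""
    w = min(round_deg, arc_deg / 3.0)
    ends = np.linspace(0.0, arc_deg, n)
    d = np.minimum(ends, arc_deg - ends)
    return np.where(d >= w, 1.0, 0.5 * (1 - np.cos(np.pi * d / w)))


def _sector_polygon(r_inner, r_outer, theta_deg) -> Contour:
    """Annular sector between two radial functions sampled on theta_deg."""
    th = np.radians(theta_deg)
    inner = np.column_stack([r_inner * np.cos(th), r_inner * np.sin(th)])
    outer = np.column_stack([r_outer * np.cos(th), r_outer * np.sin(th)])
    return Contour(np.vstack([inner, outer[::-1]]))


def generate_lesion(group: str, config: CohortConfig,
                    rng: np.random.Generator,
                    lesion_id: str = "lesion") -> Lesion:
    """Draw one lesion of the given group; resamples invalid geometries."""
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    p: GroupParams = config.groups[group]
    last_err = None
    for _ in range(20):
        try:
            return _generate_once(group, p, config, rng, lesion_id)
        except ValueError as err:   # invalid sampled geometry; try again
            last_err = err
    raise ValueError(f"could not generate a valid lesion: {last_err}")


def _generate_once(group, p, config, rng, lesion_id) -> Lesion:
    r0 = _trunc_normal(rng, *p.lumen_radius_mm, lo=0.6, hi=1.5)
    min_fct = _trunc_normal(rng, *p.min_fct_um, lo=20.0)
    cap_max = _trunc_normal(rng, *p.cap_max_um, lo=min_fct + 15.0)
    arc = _trunc_normal(rng, *p.max_lipid_arc_deg, lo=30.0, hi=360.0)
    depth = _trunc_normal(rng, *p.lipid_depth_mm, lo=0.15, hi=0.7)
    lipid_length = _trunc_normal(rng, *p.lipid_length_mm, lo=1.0)
    theta0 = rng.uniform(0.0, 360.0)
    macrophages = bool(rng.random() < p.macrophage_prob)
    want_calc = bool(rng.random() < p.spotty_calc_prob)

    npts = config.contour_points
    th_deg = np.arange(npts) * (360.0 / npts)
    th = np.radians(th_deg)

    # smoothly perturbed lumen (low-order Fourier waviness)
    r_lum = np.full(npts, r0)
    for k in (2, 3, 4):
        amp = rng.normal(0.0, config.lumen_waviness * r0 / 2)
        phase = rng.uniform(0, 2 * np.pi)
        r_lum = r_lum + amp * np.cos(k * th + phase)

    # cap thickness: cosine taper to min_fct at the lipid mid-angle
    dth = (th_deg - theta0 + 180.0) % 360.0 - 180.0
    w = np.where(np.abs(dth) <= arc / 2,
                 np.cos(np.pi * dth / arc) ** 2, 0.0)
    t_mm = (cap_max - (cap_max - min_fct) * w) / 1000.0
    r_cap = r_lum + t_mm
    if np.any(r_cap >= OUTER_RADIUS_MM - 0.3):
        raise ValueError("cap reaches outer wall")

    lumen = Contour(np.column_stack([r_lum * np.cos(th), r_lum * np.sin(th)]))
    cap_outer = Contour(np.column_stack([r_cap * np.cos(th),
                                         r_cap * np.sin(th)]))

    # lipid core: annular sector attached to the cap outer boundary, full
    # depth over the arc with a short cosine rounding (~10 deg) at the
    # angular ends so the outline meets the cap tangentially (no sharp
    # corners, hence no artificial stress singularities)
    n_arc = max(24, int(np.ceil(arc / 360.0 * npts)))
    sec_th = theta0 + np.linspace(-arc / 2, arc / 2, n_arc)
    sec_r_in = np.interp(sec_th % 360.0, th_deg, r_cap, period=360.0)
    sec_r_out = np.minimum(sec_r_in + depth * _end_rounding(arc, n_arc),
                           OUTER_RADIUS_MM - 0.12)
    lipid = _sector_polygon(sec_r_in[1:-1], sec_r_out[1:-1], sec_th[1:-1])

    calcs = []
    spotty = False
    margin = 30.0
    free_arc = 360.0 - arc - 2 * margin
    if want_calc and free_arc > 15.0:
        calc_arc = _trunc_normal(rng, 30.0, 10.0, lo=10.0,
                                 hi=min(60.0, free_arc))
        calc_depth = _trunc_normal(rng, 0.2, 0.05, lo=0.1, hi=0.4)
        lo = theta0 + arc / 2 + margin
        hi = theta0 - arc / 2 - margin + 360.0 - calc_arc
        thc = rng.uniform(lo, hi)
        n_c = max(16, int(np.ceil(calc_arc / 360.0 * npts)))
        cth = thc + np.linspace(0.0, calc_arc, n_c)
        c_in = np.interp(cth % 360.0, th_deg, r_cap, period=360.0)
        c_out = np.minimum(c_in + calc_depth * _end_rounding(calc_arc, n_c),
                           OUTER_RADIUS_MM - 0.12)
        calcs.append(_sector_polygon(c_in[1:-1], c_out[1:-1], cth[1:-1]))
        spotty = True

    geom = PlaqueCrossSection(
        lumen=lumen, outer_wall=circle_contour(OUTER_RADIUS_MM, n=npts),
        cap_outer=cap_outer, lipid_cores=[lipid], calcifications=calcs)
    problems = validate_cross_section(geom)
    if problems:
        raise ValueError("; ".join(problems))

    # realized morphology, measured on the polygons
    prof = cap_thickness_profile(geom, 360)
    i_min = int(np.argmin(prof[:, 1]))
    realized_min = float(prof[i_min, 1])
    min_angle = float(prof[i_min, 0])
    realized_mean = float(prof[:, 1].mean())
    max_arc, _ = lipid_arc(geom)
    mla = lumen_area(geom)

    ruptured = group == "vulnerable"
    rupture_angle = None
    if ruptured:
        rupture_angle = (min_angle
                         + rng.normal(0.0, config.rupture_angle_noise_sd)) % 360.0

    morph = LesionMorphology(
        min_fct=realized_min, mean_fct=realized_mean,
        max_lipid_arc=float(max_arc), mean_lipid_arc=float(max_arc),
        lipid_length=lipid_length, mla=float(mla),
        macrophages_present=macrophages,
        macrophage_arc=_trunc_normal(rng, *p.macrophage_arc_deg, lo=10.0)
        if macrophages else 0.0,
        macrophage_length=_trunc_normal(rng, *p.macrophage_length_mm, lo=0.5)
        if macrophages else 0.0,
        spotty_calcification=spotty,
        ruptured=ruptured, rupture_angle=rupture_angle)
    return Lesion(lesion_id=lesion_id, group=group,
                  geometry=geom, morphology=morph)


def generate_cohort(config: CohortConfig) -> list:
    """Generate n_per_group lesions of each group from independent substreams."""
    seeds = np.random.SeedSequence(config.seed).spawn(2 * config.n_per_group)
    lesions = []
    k = 0
    for group in GROUPS:
        for i in range(config.n_per_group):
            rng = np.random.default_rng(seeds[k])
            lesions.append(generate_lesion(
                group, config, rng, lesion_id=f"{group}-{i:03d}"))
            k += 1
    return lesions


def perturb_contours(geometry: PlaqueCrossSection, noise_sd: float,
                     rng: np.random.Generator) -> PlaqueCrossSection:
    """Simulated re-segmentation: smooth correlated radial noise per contour.

    Each traced contour's vertices are displaced radially (about the lumen
    centroid) by an independent low-order Fourier field normalized to RMS
    ``noise_sd`` mm, emulating a second observer redrawing the structures.
    The outer wall is left untouched (it is a modelling convention, not a
    traced structure).  Invalid results are resampled.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return geometry
    c = geometry.lumen_centroid()

    def draw_field():
        coefs = rng.normal(0.0, 1.0, size=9)

        def f(th):
            d = np.full_like(th, coefs[0])
            for k in range(1, 5):
                d = d + coefs[2 * k - 1] * np.cos(k * th) \
                    + coefs[2 * k] * np.sin(k * th)
            rms = float(np.sqrt(np.mean(d ** 2))) or 1.0
            return d * (noise_sd / rms)
        return f

    def polar(contour):
        v = contour.vertices - c
        return np.arctan2(v[:, 1], v[:, 0]), np.hypot(v[:, 0], v[:, 1])

    def rebuild(th, rr):
        rr = np.maximum(rr, 0.05)
        return Contour(np.column_stack([c[0] + rr * np.cos(th),
                                        c[1] + rr * np.sin(th)]))

    # the inclusion inner boundary traces the cap outer boundary, so its
    # displacement blends from the cap field (inner arc) to the
    # inclusion's own field (outer arc) to keep the regions attached
    if geometry.cap_outer is not None:
        th_c, r_c = polar(geometry.cap_outer)
        order = np.argsort(th_c)
        cap_th, cap_r = th_c[order], r_c[order]

    def r_cap_at(th):
        return np.interp(th, cap_th, cap_r, period=2 * np.pi)

    for _ in range(10):
        f_lum = draw_field()
        f_cap = draw_field()
        th, r = polar(geometry.lumen)
        r_lum_new = np.maximum(r + f_lum(th), 0.05)
        lumen = rebuild(th, r_lum_new)
        ordl = np.argsort(th)
        lum_th, lum_r = th[ordl], r_lum_new[ordl]

        def r_lum_at(t):
            return np.interp(t, lum_th, lum_r, period=2 * np.pi)

        cap_outer = None
        if geometry.cap_outer is not None:
            th, r = polar(geometry.cap_outer)
            # keep at least a 20 um cap over the perturbed lumen
            r_cap_new = np.maximum(r + f_cap(th), r_lum_at(th) + 0.02)
            cap_outer = rebuild(th, r_cap_new)
            ordc = np.argsort(th)
            capn_th, capn_r = th[ordc], r_cap_new[ordc]

        def r_capnew_at(t):
            return np.interp(t, capn_th, capn_r, period=2 * np.pi)

        def wobble_inclusion(contour):
            f_own = draw_field()
            th, r = polar(contour)
            depth = r - r_cap_at(th)
            span = max(float(depth.max()), 1e-6)
            w = np.clip(depth / span, 0.0, 1.0)
            rr = r + (1 - w) * f_cap(th) + w * f_own(th)
            return rebuild(th, np.maximum(rr, r_capnew_at(th) - 1e-6))

        out = PlaqueCrossSection(
            lumen=lumen, outer_wall=geometry.outer_wall,
            cap_outer=cap_outer,
            lipid_cores=[wobble_inclusion(k) for k in geometry.lipid_cores],
            calcifications=[wobble_inclusion(k)
                            for k in geometry.calcifications])
        if not validate_cross_section(out):
            return out
    raise ValueError("could not produce a valid perturbed geometry")


def write_cohort(lesions, out_dir) -> Path:
    """Write lesion JSON files and a cohort manifest CSV; returns manifest path."""
    import csv as _csv
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for les in lesions:
        (out / f"{les.lesion_id}.json").write_text(
            lesion_to_json(les.geometry, les.morphology, les.lesion_id))
        row = {"id": les.lesion_id, "group": les.group}
        row.update(asdict(les.morphology))
        rows.append(row)
    manifest = out / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = _csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        wr.writeheader()
        wr.writerows(rows)
    return manifest
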