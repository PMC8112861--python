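"""Stress endpoints and rupture-site angular statistics.

Peak cap stress (PCS) is the highest element-centroid von Mises stress in
the fibrous cap; maximal plaque stress (MPS) the highest anywhere in the
solid cross-section.  Stresses are read at element centroids, not
extrapolated to nodes, which avoids singular-corner amplification; peak
values are therefore checked for mesh convergence rather than nodal
accuracy.  Angular locations are reported about the lumen centroid, and
rupture proximity is the wrapped angular distance (in [0, 180] deg)
between the rupture site and the stress maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fea import Mesh, StressField
from .geometry import PlaqueCrossSection, angular_position

__all__ = ["StressSummary", "RuptureCorrelation", "stress_summary",
           "angular_distance", "rupture_proximity", "polar_histogram"]


@dataclass
class StressSummary:
    """Per-lesion stress endpoints (kPa) and their angular locations (deg)."""

    peak_cap_stress: float
    pcs_angle: float
    maximal_plaque_stress: float
    mps_angle: float
    mean_displacement_fraction: float


@dataclass
class RuptureCorrelation:
    """Angular distances (deg, in [0, 180]) from rupture site to stress maxima."""

    lesion_id: str
    angle_pcs_to_rupture: float
    angle_mps_to_rupture: float


def stress_summary(field: StressField, mesh: Mesh,
                   geometry: PlaqueCrossSection,
                   include_calcifications: bool = True) -> StressSummary:
    """Extract PCS / MPS and the mean luminal displacement fraction.

    The MPS search region covers every solid element (cap, wall, lipid,
    calcification); ``include_calcifications=False`` drops the stiff
    inclusions, whose interior stress can dominate the maximum.  Argmax
    ties resolve to the lowest element index, so outputs are deterministic.
    """
    regions = mesh.element_regions()
    cap_mask = regions == "cap"
    if not np.any(cap_mask):
        raise ValueError("mesh has no fibrous cap elements")
    centroids = mesh.element_centroids()

    cap_idx = np.nonzero(cap_mask)[0]
    i_pcs = cap_idx[int(np.argmax(field.vm[cap_idx]))]
    pcs = float(field.vm[i_pcs])

    if include_calcifications:
        all_idx = np.arange(mesh.n_elements)
    else:
        all_idx = np.nonzero(regions != "calcification")[0]
    i_mps = all_idx[int(np.argmax(field.vm[all_idx]))]
    mps = float(field.vm[i_mps])

    pcs_angle = angular_position(centroids[i_pcs], geometry)
    mps_angle = angular_position(centroids[i_mps], geometry)

    u_lum = np.linalg.norm(field.displacement[mesh.lumen_nodes], axis=1)
    r_lum = np.linalg.norm(mesh.nodes[mesh.lumen_nodes] - mesh.center, axis=1)
    frac = float(u_lum.mean() / r_lum.mean())

    return StressSummary(peak_cap_stress=pcs, pcs_angle=pcs_angle,
                         maximal_plaque_stress=mps, mps_angle=mps_angle,
                         mean_displacement_fraction=frac)


def angular_distance(theta1: float, theta2: float) -> float:
    """Wrapped angular distance in degrees, in [0, 180]."""
    d = abs(theta1 - theta2) % 360.0
    return float(min(d, 360.0 - d))


def rupture_proximity(summaries, morphologies, lesion_ids=None):
    """Per-ruptured-lesion angular distances and their aggregates.

    Returns ``(correlations, aggregate)`` where ``aggregate`` holds mean,
    sd and the fraction of ruptures within 10 deg, for both the PCS and
    the MPS location.
    """
    if lesion_ids is None:
        lesion_ids = [f"lesion-{i:03d}" for i in range(len(summaries))]
    cors = []
    for lid, s, m in zip(lesion_ids, summaries, morphologies):
        if not m.ruptured:
            continue
        cors.append(RuptureCorrelation(
            lesion_id=lid,
            angle_pcs_to_rupture=angular_distance(s.pcs_angle, m.rupture_angle),
            angle_mps_to_rupture=angular_distance(s.mps_angle, m.rupture_angle)))
    if not cors:
        raise ValueError("no ruptured lesions in the cohort")
    d_pcs = np.array([c.angle_pcs_to_rupture for c in cors])
    d_mps = np.array([c.angle_mps_to_rupture for c in cors])
    agg = {
        "n_ruptured": len(cors),
        "pcs": {"mean": float(d_pcs.mean()),
                "sd": float(d_pcs.std(ddof=1)) if len(cors) > 1 else 0.0,
                "fraction_within_10deg": float(np.mean(d_pcs <= 10.0))},
        "mps": {"mean": float(d_mps.mean()),
                "sd": float(d_mps.std(ddof=1)) if len(cors) > 1 else 0.0,
                "fraction_within_10deg": float(np.mean(d_mps <= 10.0))},
    }
    return cors, agg


def polar_histogram(angles_deg, bin_width: float = 30.0) -> np.ndarray:
    """Counts of angles per [k*w, (k+1)*w) bin; bin width must divide 360."""
    nbins = 360.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    nbins = int(round(nbins))
    counts = np.zeros(nbins, dtype=int)
    for a in np.atleast_1d(np.asarray(angles_deg, float)):
        counts[int((a % 360.0) // bin_width)] += 1
    return counts
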