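"""Classical OCT vulnerability indices and composite scores.

These are the comparator features against which the mechanical endpoints
are benchmarked: the lipid volume index (mean lipid arc x lipid length),
its macrophage analogue, the Burgmaier logistic score, and the CLIMA
point score.  The regression coefficients and thresholds are taken as
published constants; features undefined for a lesion (e.g. lipid indices
of a non-lipidic plaque) are set to zero, matching the source convention.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BurgmaierCoefficients", "ClimaThresholds", "lipid_volume_index",
           "macrophage_volume_index", "burgmaier_score", "clima_score"]


@dataclass
class BurgmaierCoefficients:
    """Published logistic-score coefficients (dimensionless score units)."""

    intercept: float = -2.401
    macrophage: float = 1.568
    lipid_arc_per_90deg: float = 2.639
    lipid_length_per_mm: float = 0.255
    fct_per_10um: float = -0.738


@dataclass
class ClimaThresholds:
    """CLIMA criteria: strict inequalities, one point each."""

    mla_mm2: float = 3.5       # MLA < 3.5 mm^2
    fct_um: float = 75.0       # FCT < 75 um
    lipid_arc_deg: float = 180.0  # arc > 180 deg


def lipid_volume_index(mean_lipid_arc: float, lipid_length: float) -> float:
    """Lipid burden surrogate: mean lipid arc (deg) x lipid length (mm)."""
    if not 0.0 <= mean_lipid_arc <= 360.0:
        raise ValueError("lipid arc must be in [0, 360]")
    if lipid_length < 0:
        raise ValueError("lipid length must be >= 0")
    return mean_lipid_arc * lipid_length


def macrophage_volume_index(macrophage_arc: float,
                            macrophage_length: float) -> float:
    """Macrophage burden surrogate, defined analogously to the lipid index."""
    if not 0.0 <= macrophage_arc <= 360.0:
        raise ValueError("macrophage arc must be in [0, 360]")
    if macrophage_length < 0:
        raise ValueError("macrophage length must be >= 0")
    return macrophage_arc * macrophage_length


def burgmaier_score(macrophages_present: bool, mean_lipid_arc: float,
                    lipid_length: float, min_fct: float,
                    coefs: BurgmaierCoefficients | None = None) -> float:
    """Composite vulnerability score from the published logistic model.

    score = -2.401 + 1.568*[macrophages] + 2.639*(arc/90 deg)
            + 0.255*(length/mm) - 0.738*(min FCT/10 um)
    """
    c = coefs or BurgmaierCoefficients()
    return (c.intercept
            + c.macrophage * (1.0 if macrophages_present else 0.0)
            + c.lipid_arc_per_90deg * (mean_lipid_arc / 90.0)
            + c.lipid_length_per_mm * lipid_length
            + c.fct_per_10um * (min_fct / 10.0))


def clima_score(mla: float, min_fct: float, max_lipid_arc: float,
                macrophages_present: bool,
                thresholds: ClimaThresholds | None = None) -> int:
    """CLIMA point score, 0-4: one point per strict criterion satisfied."""
    t = thresholds or ClimaThresholds()
    return int(mla < t.mla_mm2) + int(min_fct < t.fct_um) \
        + int(max_lipid_arc > t.lipid_arc_deg) + int(bool(macrophages_present))
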