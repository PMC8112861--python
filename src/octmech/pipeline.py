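"""End-to-end experiment orchestration.

``run_experiment`` drives the full chain: synthetic cohort -> per-lesion
finite-element solve -> stress endpoints -> vulnerability features and
scores -> group comparisons, ROC / Youden / DeLong diagnostics and
rupture-proximity statistics, with CSV/JSON artifacts and optional VTK
stress fields.  ``sensitivity_analysis`` re-solves the cohort under named
material-assumption variants and compares endpoints with paired t-tests;
``interobserver_stage`` emulates a second observer re-segmenting 20% of
the plaques per group and reports ICC(1,1) of the endpoints.

A single master seed fans out to named substreams (cohort generation,
perturbation, lesion selection), so every stage is reproducible in
isolation and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, Lesion, generate_cohort, perturb_contours, write_cohort
from .fea import (MaterialProperties, SimulationConfig, build_mesh,
                  default_materials, material_variants, solve_elasticity)
from .metrics import polar_histogram, rupture_proximity, stress_summary
from .scores import (burgmaier_score, clima_score, lipid_volume_index,
                     macrophage_volume_index)
from .stats import (chi_square_2x2, delong_test, diagnostic_result,
                    fisher_exact_2x2, icc_oneway, paired_t, two_sample_t)
from .vtkio import write_vtk

__all__ = ["PipelineConfig", "ExperimentReport", "run_experiment",
           "sensitivity_analysis", "interobserver_stage", "solve_lesion"]

log = logging.getLogger("octmech.pipeline")

CONTINUOUS_FEATURES = ("peak_cap_stress", "maximal_plaque_stress",
                       "min_fct", "mean_fct", "max_lipid_arc",
                       "lipid_volume_index", "macrophage_volume_index",
                       "burgmaier_score", "clima_score")
# features where LOWER values mark vulnerability
_LOWER_POSITIVE = {"min_fct", "mean_fct"}


@dataclass
class PipelineConfig:
    """Configuration of a full experiment run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    materials: MaterialProperties = field(default_factory=default_materials)
    variants: tuple = ("wall_incompressible", "soft_calcification",
                       "bone_calcification")
    features: tuple = CONTINUOUS_FEATURES
    seed: int = 0
    out_dir: Optional[str] = None
    write_vtk: bool = False
    mps_include_calcifications: bool = True
    interobserver_noise_sd_mm: float = 0.01

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature list must be non-empty")
        unknown = set(self.features) - set(CONTINUOUS_FEATURES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        for v in self.variants:
            material_variants(self.materials, v)   # raises on unknown names

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_vtk": self.write_vtk,
            "mps_include_calcifications": self.mps_include_calcifications,
            "interobserver_noise_sd_mm": self.interobserver_noise_sd_mm,
            "variants": list(self.variants),
            "features": list(self.features),
            "cohort": {
                "n_per_group": self.cohort.n_per_group,
                "seed": self.cohort.seed,
                "rupture_angle_noise_sd_deg": self.cohort.rupture_angle_noise_sd,
                "lumen_waviness": self.cohort.lumen_waviness,
            },
            "simulation": {
                "pressure_kpa": self.simulation.pressure_kpa,
                "cap_edge_mm": self.simulation.cap_edge_mm,
                "wall_edge_mm": self.simulation.wall_edge_mm,
                "refinement": self.simulation.refinement,
            },
            "materials": {k: {"young_modulus_pa": e, "poisson_ratio": nu}
                          for k, (e, nu) in self.materials.regions.items()},
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        coh = doc.get("cohort", {})
        sim = doc.get("simulation", {})
        mats = doc.get("materials")
        kwargs = dict(
            seed=int(doc.get("seed", 0)),
            out_dir=doc.get("out_dir"),
            write_vtk=bool(doc.get("write_vtk", False)),
            mps_include_calcifications=bool(
                doc.get("mps_include_calcifications", True)),
            interobserver_noise_sd_mm=float(
                doc.get("interobserver_noise_sd_mm", 0.01)),
            cohort=CohortConfig(
                n_per_group=int(coh.get("n_per_group", 10)),
                seed=int(coh.get("seed", 0)),
                rupture_angle_noise_sd=float(
                    coh.get("rupture_angle_noise_sd_deg", 20.0)),
                lumen_waviness=float(coh.get("lumen_waviness", 0.03))),
            simulation=SimulationConfig(
                pressure_kpa=float(sim.get("pressure_kpa", 17.0)),
                cap_edge_mm=float(sim.get("cap_edge_mm", 0.05)),
                wall_edge_mm=float(sim.get("wall_edge_mm", 0.2)),
                refinement=sim.get("refinement", "fine")),
        )
        if "variants" in doc:
            kwargs["variants"] = tuple(doc["variants"])
        if "features" in doc:
            kwargs["features"] = tuple(doc["features"])
        if mats:
            kwargs["materials"] = MaterialProperties(
                {k: (float(v["young_modulus_pa"]), float(v["poisson_ratio"]))
                 for k, v in mats.items()})
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        _atomic_write(Path(path), yaml.safe_dump(self.to_dict(),
                                                 sort_keys=True))


@dataclass
class ExperimentReport:
    """Bundle of every table and report produced by one run."""

    lesions: list
    metrics: pd.DataFrame
    features: pd.DataFrame
    group_comparison: pd.DataFrame
    diagnostics: dict
    delong: pd.DataFrame
    rupture: dict
    polar_bins: dict
    manifest: dict


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    names = ("cohort", "perturb", "select")
    return {name: child for name, child in zip(names, children)}


def _seed_int(seed_seq) -> int:
    return int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)


def solve_lesion(lesion: Lesion, materials: MaterialProperties,
                 sim: SimulationConfig, include_calc: bool = True):
    """Mesh, solve and summarize one lesion; returns (mesh, field, summary)."""
    mesh = build_mesh(lesion.geometry, sim)
    fld = solve_elasticity(mesh, materials, sim)
    summ = stress_summary(fld, mesh, lesion.geometry,
                          include_calcifications=include_calc)
    return mesh, fld, summ


def _feature_table(lesions, summaries) -> pd.DataFrame:
    rows = []
    for les, s in zip(lesions, summaries):
        m = les.morphology
        lvi = lipid_volume_index(m.mean_lipid_arc, m.lipid_length)
        mvi = macrophage_volume_index(m.macrophage_arc, m.macrophage_length)
        rows.append({
            "id": les.lesion_id, "group": les.group,
            "ruptured": int(m.ruptured),
            "peak_cap_stress": s.peak_cap_stress,
            "maximal_plaque_stress": s.maximal_plaque_stress,
            "pcs_angle": s.pcs_angle, "mps_angle": s.mps_angle,
            "mean_displacement_fraction": s.mean_displacement_fraction,
            "min_fct": m.min_fct, "mean_fct": m.mean_fct,
            "max_lipid_arc": m.max_lipid_arc,
            "lipid_volume_index": lvi, "macrophage_volume_index": mvi,
            "macrophages_present": int(m.macrophages_present),
            "spotty_calcification": int(m.spotty_calcification),
            "burgmaier_score": burgmaier_score(
                m.macrophages_present, m.mean_lipid_arc,
                m.lipid_length, m.min_fct),
            "clima_score": clima_score(m.mla, m.min_fct, m.max_lipid_arc,
                                       m.macrophages_present),
        })
    return pd.DataFrame(rows)


def _group_comparison(features: pd.DataFrame) -> pd.DataFrame:
    vuln = features[features.group == "vulnerable"]
    stab = features[features.group == "stable"]
    rows = []
    for col in ("peak_cap_stress", "maximal_plaque_stress", "min_fct",
                "mean_fct", "max_lipid_arc", "lipid_volume_index",
                "macrophage_volume_index", "burgmaier_score", "clima_score"):
        t, df, p = two_sample_t(vuln[col].to_numpy(), stab[col].to_numpy())
        rows.append({"feature": col, "kind": "continuous",
                     "vulnerable_mean": vuln[col].mean(),
                     "vulnerable_sd": vuln[col].std(ddof=1),
                     "stable_mean": stab[col].mean(),
                     "stable_sd": stab[col].std(ddof=1),
                     "statistic": t, "p_value": p})
    for col in ("macrophages_present", "spotty_calcification"):
        a = int(vuln[col].sum())
        b = int(len(vuln) - a)
        c = int(stab[col].sum())
        d = int(len(stab) - c)
        p_f = fisher_exact_2x2(a, b, c, d)
        try:
            chi2, p_c = chi_square_2x2(a, b, c, d)
        except ValueError:
            chi2, p_c = float("nan"), float("nan")
        rows.append({"feature": col, "kind": "categorical",
                     "vulnerable_mean": a / max(len(vuln), 1),
                     "vulnerable_sd": float("nan"),
                     "stable_mean": c / max(len(stab), 1),
                     "stable_sd": float("nan"),
                     "statistic": chi2, "p_value": p_f,
                     "p_value_chi2": p_c})
    return pd.DataFrame(rows)


def run_experiment(config: PipelineConfig) -> ExperimentReport:
    """Run the full experiment; deterministic given ``config.seed``."""
    t_start = time.time()
    seeds = _stage_seeds(config.seed)
    cohort_cfg = replace(config.cohort, seed=_seed_int(seeds["cohort"]))
    log.info("stage=cohort n_per_group=%d", cohort_cfg.n_per_group)
    lesions = generate_cohort(cohort_cfg)

    summaries = []
    meshes = []
    fields = []
    for les in lesions:
        t0 = time.time()
        mesh, fld, summ = solve_lesion(les, config.materials,
                                       config.simulation,
                                       config.mps_include_calcifications)
        summaries.append(summ)
        meshes.append(mesh)
        fields.append(fld)
        log.info("stage=solve lesion=%s pcs=%.1f mps=%.1f wall_s=%.2f",
                 les.lesion_id, summ.peak_cap_stress,
                 summ.maximal_plaque_stress, time.time() - t0)

    features = _feature_table(lesions, summaries)
    metrics = features[["id", "group", "ruptured", "peak_cap_stress",
                        "maximal_plaque_stress", "pcs_angle", "mps_angle",
                        "mean_displacement_fraction"]].copy()
    group_cmp = _group_comparison(features)

    labels = features["ruptured"].to_numpy()
    diagnostics = {}
    if labels.min() == labels.max():
        raise ValueError("ROC stage needs both ruptured and non-ruptured "
                         "lesions (single-class cohort)")
    for feat in config.features:
        orientation = "lower" if feat in _LOWER_POSITIVE else "auto"
        d = diagnostic_result(feat, features[feat].to_numpy(), labels,
                              orientation)
        diagnostics[feat] = {
            "auc": d.curve.auc, "band": d.band, "cutoff": d.cutoff,
            "sensitivity": d.sensitivity, "specificity": d.specificity,
            "orientation": int(d.curve.orientation),
        }

    rows = []
    for i, fa in enumerate(config.features):
        for fb in config.features[i + 1:]:
            try:
                auc_a, auc_b, z, p = delong_test(
                    features[fa].to_numpy(), features[fb].to_numpy(), labels)
            except ValueError as err:
                auc_a = auc_b = z = p = float("nan")
                log.warning("delong %s vs %s failed: %s", fa, fb, err)
            rows.append({"feature_a": fa, "feature_b": fb,
                         "auc_a": auc_a, "auc_b": auc_b, "z": z, "p": p})
    delong = pd.DataFrame(rows)

    morphs = [les.morphology for les in lesions]
    cors, rupture_agg = rupture_proximity(summaries, morphs,
                                          [l.lesion_id for l in lesions])
    d_pcs = [c.angle_pcs_to_rupture for c in cors]
    d_mps = [c.angle_mps_to_rupture for c in cors]
    polar_bins = {
        "bin_width_deg": 30.0,
        "pcs": polar_histogram(d_pcs, 30.0).tolist(),
        "mps": polar_histogram(d_mps, 30.0).tolist(),
    }
    rupture = {"per_lesion": [dataclasses.asdict(c) for c in cors],
               "aggregate": rupture_agg}

    cfg_dict = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "octmech_version": __version__,
        "numpy_version": np.__version__,
        "n_lesions": len(lesions),
        "wall_time_s": round(time.time() - t_start, 2),
        "config": cfg_dict,
    }

    report = ExperimentReport(lesions=lesions, metrics=metrics,
                              features=features, group_comparison=group_cmp,
                              diagnostics=diagnostics, delong=delong,
                              rupture=rupture, polar_bins=polar_bins,
                              manifest=manifest)
    if config.out_dir:
        _write_report(report, config, meshes, fields)
    return report


def _write_report(report: ExperimentReport, config: PipelineConfig,
                  meshes, fields) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(report.lesions, out / "cohort")
    _atomic_write(out / "metrics.csv", report.metrics.to_csv(index=False))
    _atomic_write(out / "features.csv", report.features.to_csv(index=False))
    _atomic_write(out / "group_comparison.csv",
                  report.group_comparison.to_csv(index=False))
    _atomic_write(out / "delong.csv", report.delong.to_csv(index=False))
    stats_report = {"diagnostics": report.diagnostics,
                    "rupture": report.rupture,
                    "polar_bins": report.polar_bins}
    _atomic_write(out / "statistics.json",
                  json.dumps(stats_report, indent=2, sort_keys=True))
    # wall_time varies between runs; the manifest therefore keeps it out of
    # the hashed, byte-stable portion written here
    manifest = dict(report.manifest)
    manifest.pop("wall_time_s", None)
    _atomic_write(out / "run_manifest.json",
                  json.dumps(manifest, indent=2, sort_keys=True))
    if config.write_vtk:
        vdir = out / "vtk"
        vdir.mkdir(exist_ok=True)
        for les, mesh, fld in zip(report.lesions, meshes, fields):
            write_vtk(vdir / f"{les.lesion_id}.vtk", mesh, fld)


def sensitivity_analysis(config: PipelineConfig,
                         variants: Optional[tuple] = None) -> pd.DataFrame:
    """Paired comparison of stress endpoints under material variants.

    Re-solves the default cohort under each named variant and reports the
    per-variant paired t-test on PCS and MPS differences vs. the base
    materials.
    """
    variants = tuple(variants if variants is not None else config.variants)
    if not variants:
        raise ValueError("need at least one material variant")
    seeds = _stage_seeds(config.seed)
    cohort_cfg = replace(config.cohort, seed=_seed_int(seeds["cohort"]))
    lesions = generate_cohort(cohort_cfg)
    meshes = [build_mesh(les.geometry, config.simulation) for les in lesions]

    def endpoints(mats):
        pcs, mps = [], []
        for les, mesh in zip(lesions, meshes):
            fld = solve_elasticity(mesh, mats, config.simulation)
            s = stress_summary(fld, mesh, les.geometry,
                               config.mps_include_calcifications)
            pcs.append(s.peak_cap_stress)
            mps.append(s.maximal_plaque_stress)
        return np.array(pcs), np.array(mps)

    base_pcs, base_mps = endpoints(config.materials)
    rows = []
    for name in variants:
        mats = material_variants(config.materials, name)
        v_pcs, v_mps = endpoints(mats)
        for metric, base, var in (("peak_cap_stress", base_pcs, v_pcs),
                                  ("maximal_plaque_stress", base_mps, v_mps)):
            diff = var - base
            try:
                t, df, p = paired_t(diff)
            except ValueError:
                t, df, p = float("nan"), float(len(diff) - 1), float("nan")
            rows.append({"variant": name, "metric": metric,
                         "base_mean": float(base.mean()),
                         "variant_mean": float(var.mean()),
                         "mean_difference": float(diff.mean()),
                         "t": t, "p": p})
    return pd.DataFrame(rows)


def interobserver_stage(config: PipelineConfig,
                        noise_sd: Optional[float] = None) -> dict:
    """Simulated second-observer re-segmentation and ICC of the endpoints.

    20% of the plaques in each group (rounded up) are re-drawn with smooth
    radial contour noise and re-solved; ICC(1,1) is computed between the
    original and re-segmented PCS and MPS.
    """
    noise = config.interobserver_noise_sd_mm if noise_sd is None else noise_sd
    seeds = _stage_seeds(config.seed)
    cohort_cfg = replace(config.cohort, seed=_seed_int(seeds["cohort"]))
    lesions = generate_cohort(cohort_cfg)
    select_rng = np.random.default_rng(seeds["select"])
    perturb_rng = np.random.default_rng(seeds["perturb"])

    chosen = []
    for group in ("stable", "vulnerable"):
        members = [l for l in lesions if l.group == group]
        k = math.ceil(0.2 * len(members))
        idx = select_rng.choice(len(members), size=k, replace=False)
        chosen += [members[i] for i in sorted(idx)]

    pairs_pcs, pairs_mps = [], []
    for les in chosen:
        _, _, s0 = solve_lesion(les, config.materials, config.simulation,
                                config.mps_include_calcifications)
        geom2 = perturb_contours(les.geometry, noise, perturb_rng)
        les2 = Lesion(les.lesion_id + "-obs2", les.group, geom2,
                      les.morphology)
        _, _, s1 = solve_lesion(les2, config.materials, config.simulation,
                                config.mps_include_calcifications)
        pairs_pcs.append([s0.peak_cap_stress, s1.peak_cap_stress])
        pairs_mps.append([s0.maximal_plaque_stress, s1.maximal_plaque_stress])

    out = {"noise_sd_mm": noise, "n_reviewed": len(chosen),
           "lesion_ids": [l.lesion_id for l in chosen]}
    if noise == 0:
        out["icc_pcs"] = 1.0
        out["icc_mps"] = 1.0
    else:
        out["icc_pcs"] = icc_oneway(np.asarray(pairs_pcs))
        out["icc_mps"] = icc_oneway(np.asarray(pairs_mps))
    return out
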