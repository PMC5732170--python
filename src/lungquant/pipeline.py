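"""End-to-end orchestration: phantom/scan -> segmentation -> exemplar
classification -> peritumoral parenchyma scoring -> cohort statistics.

`run_nodule` composes the per-nodule stages into one record; `run_cohort`
turns a cohort table into the statistical report (contingency tests,
stepwise EGFR model, ROC cutoffs at the configured sensitivity, and survival
by risk group).  Errors are re-raised with the failing stage named so a long
batch points at the culprit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import exemplars as ex
from . import imaging, parenchyma, stats
from .grid import CTVolume, SeedPoint, VoxelMask

logger = logging.getLogger("lungquant")

__all__ = ["PipelineConfig", "StageError", "run_nodule", "run_cohort"]


class StageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; every numeric default is documented on the
    stage that consumes it."""

    grow_hu_low: float = imaging.DEFAULT_GROW_BOUNDS[0]
    grow_hu_high: float = imaging.DEFAULT_GROW_BOUNDS[1]
    grow_connectivity: int = 26
    shell_distance_mm: float = 10.0
    parenchyma_thresholds: parenchyma.ParenchymaThresholds = field(
        default_factory=parenchyma.ParenchymaThresholds
    )
    voi_min_occupancy: float = 0.3
    stepwise_entry_p: float = 0.05
    stepwise_stay_p: float = 0.05
    roc_target_sensitivity: float = 0.80
    seed: int = 0


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, e) from e
        return wrapper
    return deco


def run_nodule(
    config: PipelineConfig,
    volume: CTVolume,
    seed_point: SeedPoint,
    model: ex.ExemplarModel,
    lung: VoxelMask | None = None,
) -> dict[str, Any]:
    """Analyse one nodule end to end; deterministic given the config seed.

    Returns a flat record: the nine glyph percentages, composite features,
    registered cutoff flags, shell parenchyma summary and nodule volume (cc).
    """
    if lung is None:
        lung = _stage("segment_lung")(imaging.segment_lung)(volume)
    if not lung.data[seed_point.as_tuple()]:
        raise StageError("grow_nodule", ValueError(
            f"seed {seed_point.as_tuple()} is outside the lung mask"))
    nodule = _stage("grow_nodule")(imaging.grow_nodule)(
        volume, seed_point, config.grow_hu_low, config.grow_hu_high,
        config.grow_connectivity)
    labels = _stage("classify_voxels")(ex.classify_voxels)(volume, nodule, model)
    glyph = ex.compute_glyph(labels, nodule)
    comps = ex.composite_features(glyph)
    shell = _stage("peritumoral_shell")(imaging.peritumoral_shell)(
        nodule, lung, config.shell_distance_mm)
    summary = _stage("summarize_parenchyma")(parenchyma.summarize_parenchyma)(
        volume, shell, config.parenchyma_thresholds,
        min_occupancy=config.voi_min_occupancy)
    record: dict[str, Any] = {c.lower(): glyph[c] for c in ex.CANONICAL_COLORS}
    record.update({
        "viro": comps.viro, "yp": comps.yp, "bcg": comps.bcg,
        "y_plus_g": comps.y_plus_g,
        "flag_viro_le_71": ex.apply_cutoff(comps, "VIRO"),
        "flag_yp_ge_23.5": ex.apply_cutoff(comps, "YP"),
        "frac_N": summary.fraction_normal, "frac_LA": summary.fraction_LA,
        "frac_GG": summary.fraction_GG, "frac_R": summary.fraction_reticular,
        "frac_HC": summary.fraction_HC,
        "fibrosis": summary.fibrosis, "low_attenuation": summary.low_attenuation,
        "nodule_cc": imaging.mask_volume_cc(nodule),
    })
    logger.info("nodule at %s: VIRO %.1f%%, fibrosis %.3f, volume %.2f cc",
                seed_point.as_tuple(), comps.viro, summary.fibrosis,
                record["nodule_cc"])
    return record


REQUIRED_COHORT_COLUMNS = ("egfr", "smoking", "y", "g", "fibrosis",
                           "dfs_time", "dfs_event", "risk_group")


def run_cohort(config: PipelineConfig, cohort: pd.DataFrame) -> dict[str, Any]:
    """Cohort-level statistical report.

    Emits contingency tests of EGFR against smoking status, the stepwise
    EGFR logistic model over the exemplar/fibrosis candidates, ROC cutoffs
    for V-I-R-O and Y-P at the configured target sensitivity, and risk-group
    survival (Kaplan-Meier curves plus a Cox likelihood-ratio test).
    """
    if len(cohort) == 0:
        raise StageError("run_cohort", ValueError("empty cohort table"))
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise StageError("run_cohort", KeyError(f"missing columns: {missing}"))
    y = cohort["egfr"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise StageError("run_cohort", ValueError("EGFR outcome has one class"))
    report: dict[str, Any] = {}

    smoking_tab = pd.crosstab(cohort["smoking"], cohort["egfr"])
    try:
        report["egfr_vs_smoking_fisher_p"] = stats.fisher_exact(smoking_tab)
    except ValueError:
        report["egfr_vs_smoking_chi2_p"] = stats.chi_square_test(smoking_tab)[1]

    candidates = pd.DataFrame({
        "y": cohort["y"], "g": cohort["g"],
        "never_smoker": (cohort["smoking"] == "never").astype(float),
        "fibrosis": cohort["fibrosis"],
    })
    fit = stats.stepwise_select(candidates, y, config.stepwise_entry_p,
                                config.stepwise_stay_p)
    report["stepwise"] = {
        "selected": fit.variables,
        "coefficients": fit.params,
        "pvalues": fit.pvalues,
        "trace": fit.selection_trace,
    }

    report["cutoffs"] = {}
    for feat, direction in (("viro", "lower"), ("yp", "higher")):
        if feat in cohort.columns:
            roc = stats.roc_curve(cohort[feat], y, direction=direction)
            thr, sens, spec = stats.threshold_at_sensitivity(
                roc, config.roc_target_sensitivity)
            report["cutoffs"][feat] = {
                "threshold": thr, "sensitivity": sens, "specificity": spec,
                "auc": roc.auc,
            }

    survival = {}
    for grp, sub in cohort.groupby("risk_group"):
        km = stats.km_estimator(sub["dfs_time"], sub["dfs_event"])
        survival[str(grp)] = km.to_dict(orient="list")
    report["km_by_risk_group"] = survival
    groups = cohort["risk_group"].astype("category").cat.codes.to_numpy(dtype=float)
    if np.ptp(groups) > 0 and cohort["dfs_event"].any():
        cox = stats.cox_lrt(cohort["dfs_time"], cohort["dfs_event"], groups)
        report["cox_risk_group"] = {
            "hazard_ratio": cox["hazard_ratio"], "p_value": cox["p_value"]}
    logger.info("cohort report: stepwise selected %s", fit.variables)
    return report
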