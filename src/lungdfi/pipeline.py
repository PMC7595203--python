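"""End-to-end in-memory pipeline: cohort -> scans -> modalities -> report.

One animal at one time point runs through: phantom rendering from its drawn
signal targets and pathology, reference and sample stepping-scan simulation,
modality retrieval, pneumothorax screening, ROI quantification, and
left-main-bronchus tracing/classification.  Cohort wrappers batch this and
assemble the cohort-level tables and statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bronchus as br
from . import roi as roi_mod
from .forward import SystemConfig, simulate_scan
from .phantom import (
    AnimalRecord,
    CohortParams,
    GeometryParams,
    build_thorax_phantom,
    sample_cohort,
    sample_longitudinal_subgroup,
)
from .retrieval import ModalityImages, retrieve
from .stats import CohortStats, apply_exclusions, summarize_cohort

__all__ = ["PipelineThresholds", "run_animal_timepoint", "run_tp1_cohort", "run_tp2_subgroup", "CohortRun"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineThresholds:
    """Config-exposed detector/classifier settings."""

    bone_threshold: float | None = None  # None -> adaptive
    bone_morph_radius: int = 2
    presmooth_scale: float = 2.0
    tau_darkfield: float = 0.3
    tau_absorption: float = 0.5
    stenosis_theta: float = 0.7
    distal_margin_px: float = 5.0
    cuff_window_px: float = 15.0


@dataclass
class CohortRun:
    """Everything one cohort pipeline run produced."""

    records: list[AnimalRecord]
    roi_table: pd.DataFrame
    classification_table: pd.DataFrame
    stats: CohortStats


def run_animal_timepoint(
    record: AnimalRecord,
    timepoint: str,
    system: SystemConfig,
    geometry: GeometryParams | None = None,
    thresholds: PipelineThresholds | None = None,
    keep_images: bool = False,
) -> AnimalRecord:
    """Simulate and analyse one animal at one time point, in place.

    Excluded-by-death animals are skipped (no usable scan exists);
    pneumothorax animals are imaged and screened but not quantified.
    """
    geometry = geometry or GeometryParams()
    thresholds = thresholds or PipelineThresholds()
    if record.excluded_reason == "death":
        return record

    pathology = record.pathology[timepoint]
    targets = record.targets[timepoint]
    phantom = build_thorax_phantom(
        geometry, pathology, seed=record.seed,
        lung_targets={"left": targets["transplanted"], "right": targets["control"]},
    )
    rng = np.random.default_rng(np.random.SeedSequence([record.seed, 0 if timepoint == "TP1" else 1]))
    reference = simulate_scan(None, system, shape=phantom.shape, rng=rng)
    sample = simulate_scan(phantom, system, rng=rng)
    modalities = retrieve(sample, reference)

    ptx = roi_mod.detect_pneumothorax(
        modalities, phantom.anatomy_masks["left_lung"],
        tau_darkfield=thresholds.tau_darkfield, tau_absorption=thresholds.tau_absorption,
    )
    record.pneumothorax_detected[timepoint] = ptx
    if keep_images:
        record.phantoms[timepoint] = phantom
        record.modalities[timepoint] = modalities
    if ptx or record.excluded_reason == "pneumothorax":
        if ptx and record.excluded_reason == "none":
            record.excluded_reason = "pneumothorax"
        return record

    masks = roi_mod.build_lung_masks(
        modalities, phantom.anatomy_masks,
        threshold=thresholds.bone_threshold,
        morph_radius=thresholds.bone_morph_radius,
        smooth_scale=thresholds.presmooth_scale,
    )
    record.roi_means[timepoint] = roi_mod.quantify_animal(modalities, masks, record.animal_id)

    record.bronchus_call[timepoint] = classify_left_bronchus(
        modalities, phantom.meta, thresholds=thresholds,
        pixel_size_um=phantom.pixel_size_um,
    )
    return record


def classify_left_bronchus(
    modalities: ModalityImages,
    phantom_meta: dict,
    pixel_size_um: float,
    thresholds: PipelineThresholds | None = None,
):
    """Trace the left main bronchus in the phase image and classify it."""
    thresholds = thresholds or PipelineThresholds()
    phase = modalities.phase
    seed = phantom_meta["seed_point"]
    direction = phantom_meta["seed_direction"]
    cuff_xy = phantom_meta["cuff_xy"]
    scale = pixel_size_um / 29.0  # px radii are defined on the 29 um raster
    try:
        cl = br.trace_bronchus(
            phase, seed, direction,
            expected_radius_px=max(20.0 / scale, 4.0),
        )
    except ValueError:
        # no lumen at all at the seed: counts as a truncated airway
        return br.BronchusCall(label="truncation", min_diameter_at_cuff_mm=0.0,
                               proximal_reference_diameter_mm=float("nan"), distal_visible=False)
    profile = br.build_profile(phase, cl, cuff_xy, pixel_size_um)
    # did the trace actually reach the cuff?
    end_to_cuff = np.linalg.norm(np.asarray(cl[-1]) - np.asarray(cuff_xy))
    s_end = profile.arclength_px[-1]
    s_cuff = profile.arclength_px[profile.cuff_index]
    cuff_reached = (s_end > s_cuff + thresholds.distal_margin_px) or end_to_cuff < thresholds.distal_margin_px
    return br.classify_bronchus(
        profile, theta=thresholds.stenosis_theta,
        distal_margin_px=thresholds.distal_margin_px,
        cuff_window_px=thresholds.cuff_window_px,
        cuff_reached=cuff_reached,
    )


def _tables(records: list[AnimalRecord], timepoints) -> tuple[pd.DataFrame, pd.DataFrame]:
    roi_rows, cls_rows = [], []
    for r in records:
        for tp in timepoints:
            if tp in r.roi_means:
                m = r.roi_means[tp]
                roi_rows.append({
                    "animal_id": r.animal_id, "timepoint": tp,
                    "transplanted_absorption": m.transplanted_absorption,
                    "transplanted_darkfield": m.transplanted_darkfield,
                    "control_absorption": m.control_absorption,
                    "control_darkfield": m.control_darkfield,
                    "n_pixels_transplanted": m.n_pixels_transplanted,
                    "n_pixels_control": m.n_pixels_control,
                })
            if tp in r.bronchus_call:
                c = r.bronchus_call[tp]
                cls_rows.append({
                    "animal_id": r.animal_id, "timepoint": tp, "label": c.label,
                    "min_diameter_at_cuff_mm": c.min_diameter_at_cuff_mm,
                    "proximal_reference_diameter_mm": c.proximal_reference_diameter_mm,
                    "distal_visible": c.distal_visible,
                    "true_kind": r.pathology[tp].kind,
                })
    roi_cols = ["animal_id", "timepoint", "transplanted_absorption", "transplanted_darkfield",
                "control_absorption", "control_darkfield", "n_pixels_transplanted", "n_pixels_control"]
    cls_cols = ["animal_id", "timepoint", "label", "min_diameter_at_cuff_mm",
                "proximal_reference_diameter_mm", "distal_visible", "true_kind"]
    return (pd.DataFrame(roi_rows, columns=roi_cols), pd.DataFrame(cls_rows, columns=cls_cols))


def run_tp1_cohort(
    params: CohortParams,
    system: SystemConfig | None = None,
    geometry: GeometryParams | None = None,
    thresholds: PipelineThresholds | None = None,
) -> CohortRun:
    """Full first-time-point pipeline over a sampled cohort."""
    system = system or SystemConfig(noise="poisson")
    records = sample_cohort(params)
    for r in records:
        run_animal_timepoint(r, params.timepoint, system, geometry, thresholds)
        logger.debug("processed %s", r.animal_id)
    roi_table, cls_table = _tables(records, (params.timepoint,))
    cls_tp1 = cls_table[cls_table.timepoint == params.timepoint]
    stats = summarize_cohort(records, (params.timepoint,), classifications=cls_tp1)
    return CohortRun(records=records, roi_table=roi_table, classification_table=cls_table, stats=stats)


def run_tp2_subgroup(
    params_tp1: CohortParams,
    params_tp2: CohortParams,
    system: SystemConfig | None = None,
    geometry: GeometryParams | None = None,
    thresholds: PipelineThresholds | None = None,
    timepoints=("TP1", "TP2"),
) -> CohortRun:
    """Longitudinal pipeline over the rescanned subgroup."""
    system = system or SystemConfig(noise="poisson")
    records = sample_longitudinal_subgroup(params_tp1, params_tp2)
    for r in records:
        for tp in timepoints:
            run_animal_timepoint(r, tp, system, geometry, thresholds)
    roi_table, cls_table = _tables(records, timepoints)
    stats = summarize_cohort(records, timepoints)
    return CohortRun(records=records, roi_table=roi_table, classification_table=cls_table, stats=stats)
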