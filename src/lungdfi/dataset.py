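"""On-disk dataset layout, run configuration and the staged pipeline commands.

A simulated study lives in one directory::

    <out>/
      manifest.json                  cohort draw, seeds, pathology, config
      animals/<id>/<tp>/
        sample.tif, reference.tif    stepping stacks (multi-page float32,
                                     frame order = step order)
        truth_transmission.tif, truth_extinction.tif, truth_phase.tif
        masks.tif                    labelled anatomy (uint8)
        meta.json                    seed point, cuff position, targets
        absorption.tif, darkfield.tif, phase.tif, quality.tif   (retrieve)
      roi_means.csv                  (quantify)
      bronchus_calls.csv             (classify)
      cohort_stats.csv / .json       (report)

Every stage reads only what the previous stage wrote, so the pipeline can be
re-entered at any point; identical configurations reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import roi as roi_mod
from .forward import SteppingStack, SystemConfig, simulate_scan
from .phantom import (
    AnimalRecord,
    CohortParams,
    GeometryParams,
    PathologySpec,
    build_thorax_phantom,
    cohort_manifest,
    sample_cohort,
    sample_longitudinal_subgroup,
    tp1_preset,
    tp2_subgroup_presets,
)
from .pipeline import PipelineThresholds, classify_left_bronchus
from .retrieval import ModalityImages, retrieve
from .stats import summarize_cohort

__all__ = [
    "RunConfig", "cmd_simulate", "cmd_retrieve", "cmd_quantify", "cmd_classify", "cmd_report",
]

logger = logging.getLogger(__name__)

_MASK_LABELS = {"body": 1, "left_lung": 2, "right_lung": 3, "bone": 4,
                "bronchus_left": 5, "bronchus_right": 6, "cuff": 7}


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration.

    Re-running any stage with an identical RunConfig reproduces identical
    outputs (byte-identical manifests, numerically identical tables).
    """

    seed: int = 0
    cohort_preset: str = "TP1"  # TP1 | TP2
    system: SystemConfig = field(default_factory=lambda: SystemConfig(noise="poisson"))
    geometry: GeometryParams = field(default_factory=GeometryParams)
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    cohort: CohortParams | None = None  # overrides the preset when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort_preset not in ("TP1", "TP2"):
            raise ValueError("cohort_preset must be 'TP1' or 'TP2'")

    def resolve_records(self) -> tuple[list[AnimalRecord], tuple[str, ...]]:
        if self.cohort is not None:
            params = dataclasses.replace(self.cohort, seed=self.seed)
            return sample_cohort(params), (params.timepoint,)
        if self.cohort_preset == "TP1":
            return sample_cohort(tp1_preset(self.seed)), ("TP1",)
        p1, p2 = tp2_subgroup_presets(self.seed)
        return sample_longitudinal_subgroup(p1, p2), ("TP1", "TP2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["system"] = dataclasses.asdict(self.system)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["cohort"] = dataclasses.asdict(self.cohort) if self.cohort else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "system" in d and d["system"] is not None:
            sysd = dict(d["system"])
            for key in ("grating_periods_um", "grating_heights_um"):
                if key in sysd:
                    sysd[key] = tuple(sysd[key])
            d["system"] = SystemConfig(**sysd)
        if "geometry" in d and d["geometry"] is not None:
            g = dict(d["geometry"])
            if "shape" in g:
                g["shape"] = tuple(g["shape"])
            d["geometry"] = GeometryParams(**g)
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = PipelineThresholds(**d["thresholds"])
        if d.get("cohort"):
            c = dict(d["cohort"])
            for key in ("transplanted_absorption", "transplanted_darkfield",
                        "control_absorption", "control_darkfield"):
                c[key] = tuple(c[key])
            d["cohort"] = CohortParams(**c)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _encode_masks(anatomy_masks: dict) -> np.ndarray:
    out = np.zeros(next(iter(anatomy_masks.values())).shape, dtype=np.uint8)
    for name, code in _MASK_LABELS.items():
        out[anatomy_masks[name]] = code
    return out


def _decode_masks(labels: np.ndarray) -> dict:
    return {name: labels == code for name, code in _MASK_LABELS.items()}


def _animal_dir(root: Path, animal_id: str, tp: str) -> Path:
    return Path(root) / "animals" / animal_id / tp


def _write_tiff(path: Path, array: np.ndarray, dtype=np.float32) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=dtype), photometric="minisblack")


def cmd_simulate(config: RunConfig, out: Path, overwrite: bool = False) -> Path:
    """Generate the cohort and write stepping stacks + ground truth to disk."""
    out = Path(out)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    records, timepoints = config.resolve_records()

    for r in records:
        if r.excluded_reason == "death":
            continue
        for tp in timepoints:
            if tp not in r.targets:
                continue
            targets = r.targets[tp]
            phantom = build_thorax_phantom(
                config.geometry, r.pathology[tp], seed=r.seed,
                lung_targets={"left": targets["transplanted"], "right": targets["control"]},
            )
            rng = np.random.default_rng(np.random.SeedSequence([r.seed, 0 if tp == "TP1" else 1]))
            reference = simulate_scan(None, config.system, shape=phantom.shape, rng=rng)
            sample = simulate_scan(phantom, config.system, rng=rng)
            adir = _animal_dir(out, r.animal_id, tp)
            adir.mkdir(parents=True, exist_ok=True)
            _write_tiff(adir / "sample.tif", sample.frames)
            _write_tiff(adir / "reference.tif", reference.frames)
            _write_tiff(adir / "truth_transmission.tif", phantom.transmission_map)
            _write_tiff(adir / "truth_extinction.tif", phantom.extinction_map)
            _write_tiff(adir / "truth_phase.tif", phantom.phase_map)
            tifffile.imwrite(adir / "masks.tif", _encode_masks(phantom.anatomy_masks))
            meta = {
                "animal_id": r.animal_id,
                "timepoint": tp,
                "pixel_size_um": phantom.pixel_size_um,
                "seed_point": phantom.meta["seed_point"],
                "seed_direction": phantom.meta["seed_direction"],
                "cuff_xy": phantom.meta["cuff_xy"],
                "targets": targets,
                "pathology_kind": r.pathology[tp].kind,
                "config_hash": config.system.config_hash,
            }
            (adir / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
        logger.info("simulated %s", r.animal_id)

    manifest = {
        "config": config.to_dict(),
        "timepoints": list(timepoints),
        "cohort": json.loads(cohort_manifest(records)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out


def _load_manifest(root: Path) -> dict:
    path = Path(root) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}; run simulate first")
    return json.loads(path.read_text())


def _iter_scan_dirs(root: Path):
    manifest = _load_manifest(root)
    for entry in manifest["cohort"]:
        for tp in manifest["timepoints"]:
            adir = _animal_dir(root, entry["animal_id"], tp)
            if adir.exists():
                yield entry, tp, adir


def cmd_retrieve(out: Path) -> Path:
    """Retrieve the three modalities for every stored scan pair."""
    out = Path(out)
    manifest = _load_manifest(out)
    config_hash = RunConfig.from_dict(manifest["config"]).system.config_hash
    n = 0
    for entry, tp, adir in _iter_scan_dirs(out):
        spath, rpath = adir / "sample.tif", adir / "reference.tif"
        if not rpath.exists():
            raise FileNotFoundError(f"missing reference stack for {entry['animal_id']} {tp}: {rpath}")
        sample = SteppingStack(tifffile.imread(spath), role="sample", config_hash=config_hash)
        reference = SteppingStack(tifffile.imread(rpath), role="reference", config_hash=config_hash)
        mod = retrieve(sample, reference)
        _write_tiff(adir / "absorption.tif", mod.absorption)
        _write_tiff(adir / "darkfield.tif", mod.darkfield)
        _write_tiff(adir / "phase.tif", mod.phase)
        tifffile.imwrite(adir / "quality.tif", mod.quality_mask.astype(np.uint8))
        n += 1
        logger.info("retrieved %s %s (%d done)", entry["animal_id"], tp, n)
    return out


def _load_modalities(adir: Path) -> ModalityImages:
    if not (adir / "absorption.tif").exists():
        raise FileNotFoundError(f"no retrieved modalities under {adir}; run retrieve first")
    return ModalityImages(
        absorption=tifffile.imread(adir / "absorption.tif").astype(np.float64),
        darkfield=tifffile.imread(adir / "darkfield.tif").astype(np.float64),
        phase=tifffile.imread(adir / "phase.tif").astype(np.float64),
        quality_mask=tifffile.imread(adir / "quality.tif").astype(bool),
    )


def cmd_quantify(out: Path) -> Path:
    """Screen for pneumothorax and write the per-animal ROI table."""
    out = Path(out)
    manifest = _load_manifest(out)
    cfg = RunConfig.from_dict(manifest["config"])
    th = cfg.thresholds
    rows = []
    for entry, tp, adir in _iter_scan_dirs(out):
        mod = _load_modalities(adir)
        masks = _decode_masks(tifffile.imread(adir / "masks.tif"))
        ptx = roi_mod.detect_pneumothorax(mod, masks["left_lung"],
                                          tau_darkfield=th.tau_darkfield,
                                          tau_absorption=th.tau_absorption)
        if ptx or entry["excluded_reason"] != "none":
            continue
        lung_masks = roi_mod.build_lung_masks(
            mod, masks, threshold=th.bone_threshold,
            morph_radius=th.bone_morph_radius, smooth_scale=th.presmooth_scale,
        )
        m = roi_mod.quantify_animal(mod, lung_masks, entry["animal_id"])
        rows.append({
            "animal_id": entry["animal_id"], "timepoint": tp,
            "transplanted_absorption": m.transplanted_absorption,
            "transplanted_darkfield": m.transplanted_darkfield,
            "control_absorption": m.control_absorption,
            "control_darkfield": m.control_darkfield,
            "n_pixels_transplanted": m.n_pixels_transplanted,
            "n_pixels_control": m.n_pixels_control,
        })
    cols = ["animal_id", "timepoint", "transplanted_absorption", "transplanted_darkfield",
            "control_absorption", "control_darkfield", "n_pixels_transplanted", "n_pixels_control"]
    pd.DataFrame(rows, columns=cols).to_csv(out / "roi_means.csv", index=False)
    return out


def cmd_classify(out: Path) -> Path:
    """Trace and classify the left main bronchus for every analysable scan."""
    out = Path(out)
    manifest = _load_manifest(out)
    cfg = RunConfig.from_dict(manifest["config"])
    rows = []
    for entry, tp, adir in _iter_scan_dirs(out):
        if entry["excluded_reason"] != "none":
            continue
        mod = _load_modalities(adir)
        meta = json.loads((adir / "meta.json").read_text())
        call = classify_left_bronchus(mod, meta, pixel_size_um=meta["pixel_size_um"],
                                      thresholds=cfg.thresholds)
        rows.append({
            "animal_id": entry["animal_id"], "timepoint": tp, "label": call.label,
            "min_diameter_at_cuff_mm": call.min_diameter_at_cuff_mm,
            "proximal_reference_diameter_mm": call.proximal_reference_diameter_mm,
            "distal_visible": call.distal_visible,
            "true_kind": meta["pathology_kind"],
        })
    cols = ["animal_id", "timepoint", "label", "min_diameter_at_cuff_mm",
            "proximal_reference_diameter_mm", "distal_visible", "true_kind"]
    pd.DataFrame(rows, columns=cols).to_csv(out / "bronchus_calls.csv", index=False)
    return out


def _records_from_tables(manifest: dict, roi: pd.DataFrame) -> list[AnimalRecord]:
    records = []
    for entry in manifest["cohort"]:
        patho = {tp: PathologySpec(
            kind=p["kind"], stenosis_fraction=p["stenosis_fraction"],
            atelectasis_severity=p["atelectasis_severity"],
            distal_diameter_mm=p["distal_diameter_mm"],
        ) for tp, p in entry["pathology"].items()}
        rec = AnimalRecord(
            animal_id=entry["animal_id"], pathology=patho,
            excluded_reason=entry["excluded_reason"],
            decreased_ventilation=entry["decreased_ventilation"],
            targets=entry["targets"], severity=entry["severity"], seed=entry["seed"],
        )
        sub = roi[roi.animal_id == entry["animal_id"]]
        for _, row in sub.iterrows():
            rec.roi_means[row.timepoint] = roi_mod.RoiMeans(
                transplanted_absorption=row.transplanted_absorption,
                transplanted_darkfield=row.transplanted_darkfield,
                control_absorption=row.control_absorption,
                control_darkfield=row.control_darkfield,
                n_pixels_transplanted=int(row.n_pixels_transplanted),
                n_pixels_control=int(row.n_pixels_control),
            )
        records.append(rec)
    return records


def cmd_report(out: Path) -> Path:
    """Assemble the cohort statistics tables from the staged outputs."""
    out = Path(out)
    manifest = _load_manifest(out)
    roi_path = out / "roi_means.csv"
    if not roi_path.exists():
        raise FileNotFoundError("roi_means.csv missing; run quantify first")
    roi = pd.read_csv(roi_path)
    cls_path = out / "bronchus_calls.csv"
    cls = pd.read_csv(cls_path) if cls_path.exists() else None
    records = _records_from_tables(manifest, roi)
    timepoints = tuple(manifest["timepoints"])
    cls_first = None
    if cls is not None and len(cls):
        cls_first = cls[cls.timepoint == timepoints[0]]
        n_rows = len(roi[roi.timepoint == timepoints[0]])
        if len(cls_first) != n_rows:
            raise ValueError(
                f"stage mismatch: {n_rows} quantified vs {len(cls_first)} classified scans "
                f"at {timepoints[0]}; re-run the stages from one manifest"
            )
    stats = summarize_cohort(records, timepoints, classifications=cls_first)
    stats.comparisons.to_csv(out / "cohort_stats.csv", index=False)
    (out / "cohort_stats.json").write_text(json.dumps(stats.to_json_dict(), sort_keys=True, indent=1))
    return out
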