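"""Cohort-level statistics: exclusions, paired comparisons, pathology tallies.

Each animal contributes a paired (transplanted, control) ROI mean per
modality; comparisons use the Student t-test for paired samples, two-sided,
with no multiple-testing correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import AnimalRecord

__all__ = ["CohortStats", "apply_exclusions", "paired_t_test", "summarize_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class CohortStats:
    """Paired-comparison table and cohort counts."""

    comparisons: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "comparisons": self.comparisons.to_dict(orient="records"),
            "counts": self.counts,
        }


def apply_exclusions(records: list[AnimalRecord]) -> list[AnimalRecord]:
    """Drop excluded animals (pneumothorax, death), logging each one."""
    kept = []
    for r in records:
        if r.excluded:
            logger.info("excluding animal %s: %s", r.animal_id, r.excluded_reason)
        else:
            kept.append(r)
    if not kept and records:
        warnings.warn("all animals excluded; empty analysis set", stacklevel=2)
    return kept


def paired_t_test(x, y):
    """Two-sided Student t-test for paired samples.

    Returns ``(t, p, df)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` for
    ``d = x - y`` and ``df = n - 1``.  A degenerate zero-variance difference
    gives p = 1 when the mean difference is zero and p = 0 (with a warning)
    otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length (paired by animal)")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0, df
        warnings.warn("zero-variance non-zero difference: p set to 0", stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), 0.0, df
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, p, df


def _arm_values(records, tp, lung, modality):
    attr = f"{lung}_{modality}"
    vals = []
    for r in records:
        if tp not in r.roi_means:
            raise ValueError(f"animal {r.animal_id} has no ROI means at {tp}")
        vals.append(getattr(r.roi_means[tp], attr))
    return np.asarray(vals)


def summarize_cohort(
    records: list[AnimalRecord],
    timepoints=("TP1",),
    classifications: pd.DataFrame | None = None,
) -> CohortStats:
    """Fill the cohort report: paired tests, means +/- SD, and counts.

    Comparisons cover transplanted-vs-control at every requested time point
    and, when both TP1 and TP2 are present, the within-lung evolution of the
    rescanned subgroup.  ``classifications`` (a table with a ``label``
    column) feeds the airway-irregularity counts.
    """
    analysable = apply_exclusions(records)
    rows = []

    def add_row(name, tp_label, modality, x, y, arms):
        t, p, df = paired_t_test(x, y)
        rows.append({
            "comparison": name, "timepoint": tp_label, "modality": modality,
            "n_pairs": len(x),
            f"mean_{arms[0]}": float(np.mean(x)), f"sd_{arms[0]}": float(np.std(x, ddof=1)),
            f"mean_{arms[1]}": float(np.mean(y)), f"sd_{arms[1]}": float(np.std(y, ddof=1)),
            "t": t, "p": p, "df": df,
        })

    for tp in timepoints:
        have = [r for r in analysable if tp in r.roi_means]
        missing = [r.animal_id for r in analysable if tp not in r.roi_means]
        if missing:
            raise ValueError(f"missing ROI means at {tp} for animals {missing}")
        if not have:
            continue
        for modality in ("darkfield", "absorption"):
            x = _arm_values(have, tp, "transplanted", modality)
            y = _arm_values(have, tp, "control", modality)
            add_row("transplanted_vs_control", tp, modality, x, y, ("transplanted", "control"))

    if "TP1" in timepoints and "TP2" in timepoints:
        both = [r for r in analysable if "TP1" in r.roi_means and "TP2" in r.roi_means]
        if both:
            for lung in ("transplanted", "control"):
                for modality in ("darkfield", "absorption"):
                    x1 = _arm_values(both, "TP1", lung, modality)
                    x2 = _arm_values(both, "TP2", lung, modality)
                    add_row(f"{lung}_tp1_vs_tp2", "TP1/TP2", modality, x1, x2, ("tp1", "tp2"))

    counts = {
        "n_recipients": len(records),
        "analysed": len(analysable),
        "excluded_pneumothorax": sum(r.excluded_reason == "pneumothorax" for r in records),
        "excluded_death": sum(r.excluded_reason == "death" for r in records),
        "decreased_ventilation": sum(r.decreased_ventilation for r in analysable),
    }
    if classifications is not None and len(classifications):
        labels = classifications["label"]
        counts["stenosis"] = int((labels == "stenosis").sum())
        counts["truncation"] = int((labels == "truncation").sum())
        counts["irregular"] = counts["stenosis"] + counts["truncation"]
    assert counts["analysed"] + counts["excluded_pneumothorax"] + counts["excluded_death"] == counts["n_recipients"]
    return CohortStats(comparisons=pd.DataFrame(rows), counts=counts)
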