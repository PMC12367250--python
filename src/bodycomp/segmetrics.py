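"""Per-compartment segmentation metrics and per-case aggregation.

Five voxel-count metrics compare a predicted mask with its reference, per
compartment: Dice similarity coefficient ``2TP/(2TP+FP+FN)``, Jaccard score
``TP/(TP+FP+FN)``, true-positive fraction ``TP/(TP+FN)``, oversegmentation
rate ``FP/(TP+FN)`` and relative area difference
``|(TP+FP)-(TP+FN)|/(TP+FN) * 100``.  A compartment may be a single label or
the union of labels (derived SAT = sSAT + dSAT, VAT = IPAT + RPAT).

Conventions: a compartment empty in both masks scores DSC/Jaccard 1.0 and
reports TPF/OSR/area difference as missing (NaN), so perfect predictions on
compartment-free cases do not drag cohort averages.  The area difference is
reported as an absolute value by default; the signed variant is available
via ``signed=True``.  Metrics are computed over the 3D voxel set of a case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imgio import LabelMask

METRIC_NAMES = ("dsc", "jaccard", "tpf", "osr", "area_diff_pct")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: LabelMask, truth: LabelMask,
                     compartment: Iterable[int]) -> ConfusionCounts:
    """Voxel-wise counts after binarizing both masks to the label-id union."""
    if pred.shape != truth.shape:
        raise ValueError(f"geometry mismatch: {pred.shape} vs {truth.shape}")
    ids = list(compartment)
    p = np.isin(pred.labels, ids)
    t = np.isin(truth.labels, ids)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0  # both empty: perfect by convention
    return 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)


def jaccard(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def tpf(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return float("nan")  # undefined without reference voxels
    return c.tp / (c.tp + c.fn)


def osr(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return float("nan")
    return c.fp / (c.tp + c.fn)


def area_difference_pct(c: ConfusionCounts, signed: bool = False) -> float:
    if c.tp + c.fn == 0:
        return float("nan")
    diff = ((c.tp + c.fp) - (c.tp + c.fn)) / (c.tp + c.fn) * 100.0
    return diff if signed else abs(diff)


def metrics_from_counts(c: ConfusionCounts, signed: bool = False) -> Dict[str, float]:
    return {
        "dsc": dsc(c),
        "jaccard": jaccard(c),
        "tpf": tpf(c),
        "osr": osr(c),
        "area_diff_pct": area_difference_pct(c, signed=signed),
    }


def evaluate_case(pred: LabelMask, truth: LabelMask,
                  signed: bool = False) -> Dict[str, Dict[str, float]]:
    """All five metrics for every raw and derived compartment of the schema."""
    if pred.schema.region != truth.schema.region:
        raise ValueError("schema mismatch between prediction and truth")
    out: Dict[str, Dict[str, float]] = {}
    for name, ids in truth.schema.compartments().items():
        out[name] = metrics_from_counts(
            confusion_counts(pred, truth, ids), signed=signed)
    return out


def evaluate_slicewise(pred: LabelMask, truth: LabelMask) -> pd.DataFrame:
    """Per-slice metrics (debugging aid); rows = (slice, compartment)."""
    rows = []
    for k in range(pred.shape[0]):
        p1 = LabelMask(pred.labels[k:k + 1], pred.schema, pred.spacing)
        t1 = LabelMask(truth.labels[k:k + 1], truth.schema, truth.spacing)
        for name, m in evaluate_case(p1, t1).items():
            rows.append({"slice": k, "compartment": name, **m})
    return pd.DataFrame(rows)


def aggregate_cases(case_metrics: Sequence[Mapping[str, Mapping[str, float]]]
                    ) -> pd.DataFrame:
    """Cohort mean +/- SD per compartment and metric, cases weighted equally.

    Missing values (empty-reference compartments) are dropped per metric
    before averaging.
    """
    rows = []
    for i, cm in enumerate(case_metrics):
        for comp, m in cm.items():
            rows.append({"case": i, "compartment": comp, **m})
    df = pd.DataFrame(rows)
    agg = df.groupby("compartment")[list(METRIC_NAMES)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
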