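"""Rater-agreement statistics between automated and reference measurements.

Implements the agreement protocol used to compare automated quantification
with physician reference readings: Pearson correlation, single-measure
intraclass correlation from a two-way random-effects ANOVA under the
absolute-agreement definition (ICC(2,1)), Bland-Altman bias and 95% limits
of agreement (bias +/- 1.96 * SD of paired differences), a linear-trend test
treating ordinal grades as continuous predictors, and independent-samples
t-tests (Welch by default).  Two-sided tests, alpha = 0.05.

ICC(2,1) is computed from the ANOVA mean squares:

    (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

with n subjects, k = 2 raters, MS_R between-subject, MS_C between-rater and
MS_E residual mean squares.  The absolute-agreement form penalizes a
systematic offset between raters, unlike consistency ICC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class PairedMeasurements:
    """Per-subject paired values: rater A (model) vs rater B (reference)."""

    subject_ids: Sequence[str]
    rater_a: np.ndarray
    rater_b: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.rater_a = np.asarray(self.rater_a, dtype=np.float64)
        self.rater_b = np.asarray(self.rater_b, dtype=np.float64)
        if not (len(self.subject_ids) == len(self.rater_a) == len(self.rater_b)):
            raise ValueError("subject ids and rater arrays must align")
        if np.isnan(self.rater_a).any() or np.isnan(self.rater_b).any():
            raise ValueError("missing pairs must be filtered before analysis")

    @property
    def n(self) -> int:
        return len(self.rater_a)


def icc_2way_absolute(data: PairedMeasurements, average_measure: bool = False) -> float:
    """Single-measure ICC(2,1) (or average-measure ICC(2,k) if requested)."""
    if data.n < 3:
        raise ValueError("ICC needs >= 3 subjects")
    y = np.stack([data.rater_a, data.rater_b], axis=1)  # (n, k)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r == 0.0:
        return float("nan")  # no between-subject variance: ICC undefined
    if average_measure:
        denom = ms_r + (ms_c - ms_e) / n
    else:
        denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if denom == 0.0:
        return float("nan")
    num = ms_r - ms_e
    return float(num / denom)


def bland_altman(data: PairedMeasurements) -> Dict[str, object]:
    """Bias, 95% limits of agreement, and plot-ready (mean, diff) pairs."""
    if data.n < 2:
        raise ValueError("Bland-Altman needs >= 2 subjects")
    diff = data.rater_a - data.rater_b
    mean = (data.rater_a + data.rater_b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "n": data.n,
        "points": np.stack([mean, diff], axis=1),
    }


def pearson(data: PairedMeasurements) -> float:
    """Product-moment correlation; NaN when either rater has zero variance."""
    if data.n < 3:
        raise ValueError("Pearson r needs >= 3 subjects")
    if data.rater_a.std() == 0 or data.rater_b.std() == 0:
        return float("nan")
    r, _ = stats.pearsonr(data.rater_a, data.rater_b)
    return float(r)


def trend_test(values: Sequence[float], grades: Sequence[int]
               ) -> Dict[str, float]:
    """OLS of value on ordinal grade treated as continuous; slope + p_trend."""
    v = np.asarray(values, dtype=np.float64)
    g = np.asarray(grades, dtype=np.float64)
    if len(v) != len(g) or len(v) < 3:
        raise ValueError("need >= 3 aligned observations")
    if len(np.unique(g)) < 2:
        raise ValueError("trend test needs >= 2 distinct grades")
    res = stats.linregress(g, v)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p_trend": float(res.pvalue), "r": float(res.rvalue)}


def group_ttest(x: Sequence[float], y: Sequence[float],
                welch: bool = True) -> Dict[str, float]:
    """Two-sided independent-samples t-test (Welch default, pooled optional)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate variance: equal means are perfectly compatible
        if x.mean() == y.mean():
            return {"t": 0.0, "p": 1.0}
        return {"t": float("inf"), "p": 0.0}
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return {"t": float(t), "p": float(p)}


@dataclass
class AgreementResult:
    pearson_r: float
    icc: float
    bland_altman: Dict[str, object]
    n: int

    def as_dict(self) -> dict:
        ba = {k: v for k, v in self.bland_altman.items() if k != "points"}
        return {"pearson_r": self.pearson_r, "icc": self.icc,
                "bland_altman": ba, "n": self.n}


def agreement_summary(data: PairedMeasurements) -> AgreementResult:
    """The full agreement panel for one measured feature."""
    return AgreementResult(
        pearson_r=pearson(data),
        icc=icc_2way_absolute(data),
        bland_altman=bland_altman(data),
        n=data.n,
    )
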