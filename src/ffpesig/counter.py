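"""QC and normalization of targeted count-platform (nCounter-style) data.

Sample-level QC runs on *raw* counts: a sample fails if its average
endogenous count is <= ``min_average_count`` (default 1000) or if its
missing rate — the fraction of endogenous genes at or below the
sample's detection threshold, mean(negative controls) + 3 sd — is
>= ``max_missing_rate`` (default 0.20).  Both inequalities are closed.

Normalization then proceeds in three control-driven steps:

1. positive-control content scaling: each sample is scaled by the
   cohort mean of the positive-control geometric means divided by its
   own positive-control geometric mean (lane efficiency);
2. background subtraction: the per-sample mean of the negative
   controls is subtracted and values clamped at 0;
3. housekeeping content scaling: as step 1 but with the geometric mean
   of the housekeeping genes (RNA content).

The result is log2(x + 1) with control genes removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ControlSet, DataError, as_frame

__all__ = ["QCThresholds", "QCReport", "compute_qc", "filter_samples", "normalize_counts"]


@dataclass(frozen=True)
class QCThresholds:
    min_average_count: float = 1000.0
    max_missing_rate: float = 0.20
    neg_control_sd_multiplier: float = 3.0

    def __post_init__(self):
        if self.min_average_count <= 0:
            raise DataError("min_average_count must be positive")
        if not 0 <= self.max_missing_rate <= 1:
            raise DataError("max_missing_rate must be in [0, 1]")
        if self.neg_control_sd_multiplier < 0:
            raise DataError("neg_control_sd_multiplier must be non-negative")


@dataclass
class QCReport:
    """Per-sample QC summary; ``pass`` is true iff ``fail_reasons`` is empty."""

    summary: pd.DataFrame  # index sample_id; average_count, missing_rate, pass, fail_reasons
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def passing_samples(self) -> pd.Index:
        return self.summary.index[self.summary["pass"]]

    def to_tsv(self, path) -> None:
        out = self.summary.copy()
        out["fail_reasons"] = out["fail_reasons"].map(",".join)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def _split_endogenous(counts: pd.DataFrame, controls: ControlSet):
    endo = counts.index.difference(controls.all, sort=False)
    if len(endo) == 0:
        raise DataError("no endogenous genes: every row is a control")
    return counts.loc[endo]


def compute_qc(counts, controls: ControlSet, thresholds: QCThresholds | None = None) -> QCReport:
    """Per-sample QC of a raw count matrix.

    ``average_count`` is the mean raw count over endogenous (non-control)
    genes; the detection threshold is computed per sample from that
    sample's negative controls (sd with denominator n-1; a single
    negative control has sd 0).
    """
    thresholds = thresholds or QCThresholds()
    counts = as_frame(counts)
    vals = counts.to_numpy()
    if not np.all(np.isfinite(vals)) or np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise DataError("counts must be non-negative integers")
    neg_ids = counts.index.intersection(controls.negative)
    if len(neg_ids) == 0:
        raise DataError("count matrix contains no negative-control genes")

    endo = _split_endogenous(counts, controls)
    neg = counts.loc[neg_ids]
    avg = endo.mean(axis=0)
    sd = neg.std(axis=0, ddof=1).fillna(0.0) if len(neg_ids) > 1 else pd.Series(0.0, index=counts.columns)
    detect = neg.mean(axis=0) + thresholds.neg_control_sd_multiplier * sd
    missing = (endo.le(detect, axis=1)).mean(axis=0)

    reasons = []
    for s in counts.columns:
        r = []
        if avg[s] <= thresholds.min_average_count:
            r.append("low_average_count")
        if missing[s] >= thresholds.max_missing_rate:
            r.append("high_missing_rate")
        reasons.append(r)
    summary = pd.DataFrame({
        "average_count": avg,
        "missing_rate": missing,
        "pass": [not r for r in reasons],
        "fail_reasons": reasons,
    })
    return QCReport(summary=summary, thresholds=thresholds)


def filter_samples(counts, report: QCReport) -> pd.DataFrame:
    """Restrict a count matrix to QC-passing samples, preserving column order."""
    counts = as_frame(counts)
    missing = counts.columns.difference(report.summary.index)
    if len(missing):
        raise DataError(f"QC report does not cover samples: {list(missing)}")
    keep = [s for s in counts.columns if bool(report.summary.loc[s, "pass"])]
    if not keep:
        raise DataError("all samples failed QC: empty dataset")
    return counts[keep]


def _geometric_mean(frame: pd.DataFrame) -> pd.Series:
    # per-sample geometric mean over the rows of `frame`; 0 if any count is 0
    vals = frame.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(vals)
    gm = np.exp(logs.mean(axis=0))
    gm[np.any(vals == 0, axis=0)] = 0.0
    return pd.Series(gm, index=frame.columns)


def normalize_counts(counts, controls: ControlSet) -> pd.DataFrame:
    """Control-gene normalization of raw counts to a log2 matrix.

    See the module docstring for the three steps.  Raises when any
    sample's housekeeping geometric mean is zero (the sample cannot be
    content-normalized), naming the sample.
    """
    counts = as_frame(counts).astype(float)
    for name, ids in (("positive", controls.positive), ("negative", controls.negative),
                      ("housekeeping", controls.housekeeping)):
        if len(counts.index.intersection(ids)) == 0:
            raise DataError(f"count matrix contains no {name}-control genes")

    x = counts.copy()

    # 1. positive-control scaling
    pos_gm = _geometric_mean(x.loc[x.index.intersection(controls.positive)])
    zero = pos_gm.index[pos_gm == 0]
    if len(zero):
        raise DataError(f"zero positive-control geometric mean in sample(s): {list(zero)}")
    x = x.mul(pos_gm.mean() / pos_gm, axis=1)

    # 2. background subtraction with clamping
    background = x.loc[x.index.intersection(controls.negative)].mean(axis=0)
    x = x.sub(background, axis=1).clip(lower=0.0)

    # 3. housekeeping scaling
    hk_gm = _geometric_mean(x.loc[x.index.intersection(controls.housekeeping)])
    zero = hk_gm.index[hk_gm == 0]
    if len(zero):
        raise DataError(f"zero housekeeping geometric mean in sample(s): {list(zero)}")
    x = x.mul(hk_gm.mean() / hk_gm, axis=1)

    endo = x.loc[x.index.difference(controls.all, sort=False)]
    return np.log2(endo + 1.0)
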