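"""Metric suite for slope estimates: RMSE, accuracy, precision, Pearson r.

Conventions: a stride's error is estimate − truth (overestimates are
positive).  *Accuracy* is the mean error pooled over all strides;
*precision* is the mean over (subject, inclination) groups of the
within-group sample standard deviation of errors (ddof = 1 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import EvaluationError
from .strapdown import SlopeSeries

__all__ = [
    "MetricReport",
    "stride_errors",
    "rmse",
    "accuracy_precision",
    "pearson_r",
    "build_report",
]


def stride_errors(est: SlopeSeries) -> np.ndarray:
    """Per-stride error estimate − truth (degenerate strides excluded)."""
    if est.truth is None:
        raise EvaluationError("slope series carries no ground truth")
    v = est.valid()
    return v.slopes - v.truth


def rmse(errors: np.ndarray) -> float:
    """Root mean squared error of a per-stride error series."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise EvaluationError("empty error series")
    return float(np.sqrt(np.mean(e**2)))


def accuracy_precision(
    grouped_errors: dict[tuple, np.ndarray] | list[np.ndarray],
) -> tuple[float, float]:
    """Accuracy (pooled mean error) and precision (mean of per-group
    sample SDs) for errors grouped by (subject, inclination).

    Every group must hold at least two errors for a defined SD.
    """
    if isinstance(grouped_errors, dict):
        items = list(grouped_errors.items())
    else:
        items = list(enumerate(grouped_errors))
    if not items:
        raise EvaluationError("no groups supplied")
    pooled, sds = [], []
    for key, errs in items:
        e = np.asarray(errs, dtype=float)
        if e.size < 2:
            raise EvaluationError(
                f"group {key!r} has {e.size} error(s); need >= 2 for an SD"
            )
        pooled.append(e)
        sds.append(np.std(e, ddof=1))
    accuracy = float(np.mean(np.concatenate(pooled)))
    precision = float(np.mean(sds))
    return accuracy, precision


def pearson_r(est: np.ndarray, truth: np.ndarray) -> float:
    """Sample Pearson correlation between estimated and actual slopes."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.size != truth.size or est.size < 3:
        raise EvaluationError("need >= 3 paired values of equal length")
    if np.std(est) == 0 or np.std(truth) == 0:
        raise EvaluationError("zero variance: correlation undefined")
    return float(_stats.pearsonr(est, truth).statistic)


@dataclass
class MetricReport:
    """Per-group, per-subject and global metrics in tabular form."""

    groups: pd.DataFrame      #: one row per (subject, inclination)
    subjects: pd.DataFrame    #: one row per subject: RMSE, Pearson r, n
    global_rmse: float
    global_accuracy: float
    global_precision: float
    n_strides: int

    def to_text(self) -> str:
        lines = [
            "Per-group estimates (mean ± SD):",
            self.groups.to_string(index=False,
                                  float_format=lambda v: f"{v: .3f}"),
            "",
            "Per-subject metrics:",
            self.subjects.to_string(index=False,
                                    float_format=lambda v: f"{v: .3f}"),
            "",
            f"Global RMSE:      {self.global_rmse:.3f}",
            f"Global accuracy:  {self.global_accuracy:.3f}",
            f"Global precision: {self.global_precision:.3f}",
            f"Strides:          {self.n_strides}",
        ]
        return "\n".join(lines)


def build_report(runs: list[SlopeSeries]) -> MetricReport:
    """Aggregate labeled runs into a study-style report.

    Each run must carry truth plus ``meta['subject']`` and
    ``meta['inclination']`` labels; one run corresponds to one walk of
    one subject at one inclination.
    """
    rows = []
    for run in runs:
        if run.truth is None:
            raise EvaluationError("every run needs ground truth")
        meta = run.meta
        if "subject" not in meta or "inclination" not in meta:
            raise EvaluationError(
                "every run needs 'subject' and 'inclination' labels in meta"
            )
        v = run.valid()
        for est, tr in zip(v.slopes, v.truth):
            rows.append(
                {
                    "subject": meta["subject"],
                    "inclination": float(meta["inclination"]),
                    "estimate": est,
                    "truth": tr,
                    "error": est - tr,
                }
            )
    if not rows:
        raise EvaluationError("no strides to report")
    df = pd.DataFrame(rows)

    groups = (
        df.groupby(["subject", "inclination"], sort=True)
        .agg(
            mean=("estimate", "mean"),
            sd=("estimate", lambda x: np.std(x, ddof=1) if len(x) > 1 else np.nan),
            n=("estimate", "size"),
        )
        .reset_index()
    )
    subj_rows = []
    for subject, sub in df.groupby("subject", sort=True):
        subj_rows.append(
            {
                "subject": subject,
                "rmse": rmse(sub["error"].to_numpy()),
                "pearson_r": pearson_r(
                    sub["estimate"].to_numpy(), sub["truth"].to_numpy()
                ),
                "n": len(sub),
            }
        )
    grouped = {
        key: sub["error"].to_numpy()
        for key, sub in df.groupby(["subject", "inclination"], sort=True)
    }
    acc, prec = accuracy_precision(grouped)
    return MetricReport(
        groups=groups,
        subjects=pd.DataFrame(subj_rows),
        global_rmse=rmse(df["error"].to_numpy()),
        global_accuracy=acc,
        global_precision=prec,
        n_strides=len(df),
    )
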