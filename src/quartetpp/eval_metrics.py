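"""Evaluation statistics for simulation studies of branch support.

Support is evaluated by thresholding: for a threshold s, precision is the
fraction of branches with support >= s that are true, recall the fraction
of all true branches recovered at >= s, and FPR the fraction of all false
branches passing >= s. Branch-length accuracy uses the mean absolute
log10 error (a log error of 0.10 means branches are on average within a
factor 10**0.10, about 25%, of the truth) and the root mean squared error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SupportEvaluation",
    "support_pr_fpr",
    "length_log_error",
    "length_rmse",
]


@dataclass
class SupportEvaluation:
    """Per-threshold precision/recall/FPR (NaN for empty denominators)."""

    thresholds: list[float]
    precision: list[float]
    recall: list[float]
    fpr: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
                "fpr": self.fpr,
            }
        )


def support_pr_fpr(
    scored: Sequence[tuple[float, bool]],
    thresholds: Sequence[float],
) -> SupportEvaluation:
    """Precision, recall and FPR over a grid of support thresholds.

    ``scored`` holds (support, is_true) per branch, with is_true decided by
    presence of the branch's bipartition in the reference tree.
    """
    n_true = sum(1 for _, t in scored if t)
    n_false = len(scored) - n_true
    precision, recall, fpr = [], [], []
    for s in thresholds:
        tp = sum(1 for sup, t in scored if t and sup >= s)
        fp = sum(1 for sup, t in scored if not t and sup >= s)
        precision.append(tp / (tp + fp) if tp + fp else math.nan)
        recall.append(tp / n_true if n_true else math.nan)
        fpr.append(fp / n_false if n_false else math.nan)
    return SupportEvaluation(list(thresholds), precision, recall, fpr)


def length_log_error(
    true_lengths: Sequence[float],
    est_lengths: Sequence[float],
    exclude_nonpositive_estimates: bool = True,
) -> tuple[float, int]:
    """Mean |log10(w) - log10(w_hat)| over branches, plus exclusion count.

    True lengths must be positive. Zero or negative *estimates* (a dominant
    frequency at or below 1/3 yields an estimate of exactly 0) have no
    defined log error; by default they are excluded and counted, otherwise
    they raise.
    """
    if len(true_lengths) != len(est_lengths):
        raise ValueError("length vectors must match")
    errs = []
    excluded = 0
    for w, wh in zip(true_lengths, est_lengths):
        if w <= 0 or not math.isfinite(w):
            raise ValueError("true branch lengths must be positive and finite")
        if wh <= 0 or not math.isfinite(wh):
            if exclude_nonpositive_estimates:
                excluded += 1
                continue
            raise ValueError("non-positive estimated length in log error")
        errs.append(abs(math.log10(w) - math.log10(wh)))
    return (float(np.mean(errs)) if errs else math.nan, excluded)


def length_rmse(
    true_lengths: Sequence[float], est_lengths: Sequence[float]
) -> float:
    """Root mean squared error between true and estimated lengths."""
    if len(true_lengths) != len(est_lengths):
        raise ValueError("length vectors must match")
    w = np.asarray(true_lengths, dtype=float)
    wh = np.asarray(est_lengths, dtype=float)
    return float(np.sqrt(np.mean((w - wh) ** 2)))
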