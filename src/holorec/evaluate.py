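"""Aggregation of repeated test decisions: matched percentages and ROC/AUC.

The matched percentage summarises how often the decision rule labels a
trial segment as the reference class.  ROC curves sweep a threshold over
the test statistics collected from true-pair trials (reference vs same
class) and false-pair trials (reference vs the other class); the area under
the curve equals the Mann-Whitney probability that a random true-pair score
outranks a random false-pair score (ties counted half).  Since the F
statistic is two-sided (both very small and very large values indicate a
variance mismatch), |log F| is the natural one-sided sweep score for it;
the ECDF statistic Lambda is already one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MatchedPercentage", "RocResult", "matched_percentage", "roc_from_statistics"]


@dataclass(frozen=True)
class MatchedPercentage:
    """Accept-rate and correct-decision rate of a batch of trials, in %."""

    truth: str
    accept_pct: float
    correct_pct: float
    n_trials: int


@dataclass
class RocResult:
    """Threshold sweep, operating points and area under the ROC curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    sample_size: int | None = None


def matched_percentage(
    decisions: Sequence[str], truth: str
) -> MatchedPercentage:
    """Percentage of trials matched to the reference class by the decisions.

    For ``truth="true_class"`` the correct decision is ``accept_H0``; for
    ``truth="false_class"`` it is ``reject_H0``, and both the accept-rate
    and the correct-rejection rate (100 - accept-rate) are reported,
    explicitly labeled.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("decisions must be nonempty")
    if truth not in ("true_class", "false_class"):
        raise ValueError("truth must be 'true_class' or 'false_class'")
    bad = set(decisions) - {"accept_H0", "reject_H0"}
    if bad:
        raise ValueError(f"unknown decisions: {sorted(bad)}")
    accept = 100.0 * decisions.count("accept_H0") / len(decisions)
    correct = accept if truth == "true_class" else 100.0 - accept
    return MatchedPercentage(truth, accept, correct, len(decisions))


def roc_from_statistics(
    true_stats: Sequence[float],
    false_stats: Sequence[float],
    higher_is_positive: bool = True,
    sample_size: int | None = None,
) -> RocResult:
    """ROC curve separating false-pair from true-pair test statistics.

    The positive class is the *false pair* (a detection = flagging a
    mismatched input); with ``higher_is_positive`` the sweep classifies a
    trial as positive when its score exceeds the threshold.  The trapezoid
    AUC is computed alongside the Mann-Whitney pair-counting estimate and
    the two are required to agree to 1e-12 — they are the same quantity for
    a step ROC with thresholds at the pooled score values.
    """
    t = np.asarray(true_stats, dtype=np.float64)
    f = np.asarray(false_stats, dtype=np.float64)
    if t.size == 0 or f.size == 0:
        raise ValueError("both statistic vectors must be nonempty")
    if not higher_is_positive:
        t, f = -t, -f

    # sweep thresholds over pooled unique scores, descending, plus +inf
    thr = np.concatenate([[np.inf], np.unique(np.concatenate([t, f]))[::-1]])
    tpr = np.array([np.mean(f >= th) for th in thr])
    fpr = np.array([np.mean(t >= th) for th in thr])
    auc_trap = float(np.trapezoid(tpr, fpr))

    # Mann-Whitney: probability a random false-pair score outranks a true-pair one
    greater = np.count_nonzero(f[:, None] > t[None, :])
    ties = np.count_nonzero(f[:, None] == t[None, :])
    auc_mw = (greater + 0.5 * ties) / (f.size * t.size)
    if abs(auc_trap - auc_mw) > 1e-12:  # internal consistency guard
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} and Mann-Whitney AUC {auc_mw!r} disagree"
        )
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(auc_mw), sample_size=sample_size)
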