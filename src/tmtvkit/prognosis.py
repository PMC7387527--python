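"""Prognostic analysis: ROC/Youden cutoff, cohort split, Kaplan–Meier, log-rank.

The dichotomizing TMTV cutoff is chosen on a ROC curve by the Youden index
J = sensitivity + specificity − 1. Candidate cutoffs are the midpoints
between consecutive distinct sorted scores, plus ±∞ sentinels; a subject is
called positive when score > cutoff (strict, matching the voxel-selection
convention). AUC is the trapezoid area over (1 − specificity, sensitivity),
which equals the tie-corrected rank-sum (Mann–Whitney) statistic. Survival
in the resulting high/low groups is summarized with the product-limit
(Kaplan–Meier) estimator and compared by the two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .phantom import OutcomeRecord

__all__ = [
    "RocResult",
    "KmCurve",
    "roc_with_youden",
    "split_by_cutoff",
    "km_estimate",
    "log_rank",
]


@dataclass(frozen=True)
class RocResult:
    """ROC curve over candidate cutoffs, AUC and Youden-optimal cutoff."""

    cutoffs: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_value: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_cutoff": self.youden_cutoff,
            "youden_value": self.youden_value,
        }


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival steps at the observed event times."""

    event_times: np.ndarray  # increasing
    survival: np.ndarray  # non-increasing, in [0, 1]
    at_risk: np.ndarray
    n_events: int
    n_censored: int

    def survival_at(self, t: float) -> float:
        """S(t): the step value at or immediately before ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def roc_with_youden(
    scores: Sequence[float], labels: Sequence[bool]
) -> RocResult:
    """ROC curve, trapezoid AUC and Youden-index cutoff for a binary outcome.

    Ties in the Youden index are broken toward the smallest cutoff (the more
    sensitive split). Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative subjects")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate(([np.inf], mids[::-1], [-np.inf]))

    sens = np.empty_like(cutoffs)
    spec = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        called_pos = scores > c
        sens[i] = np.count_nonzero(called_pos & labels) / n_pos
        spec[i] = np.count_nonzero(~called_pos & ~labels) / n_neg

    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    youden = sens + spec - 1.0
    best_j = float(youden.max())
    # ties broken toward the smallest cutoff (the more sensitive split);
    # cutoffs are descending, so the last maximizer is the smallest
    pick = int(np.nonzero(youden == best_j)[0][-1])
    return RocResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(cutoffs[pick]),
        youden_value=best_j,
    )


def split_by_cutoff(
    records: Sequence[OutcomeRecord],
    scores: Sequence[float],
    cutoff: float,
) -> tuple[list[OutcomeRecord], list[OutcomeRecord]]:
    """Partition a cohort into (high, low) groups by score > cutoff."""
    records = list(records)
    scores = np.asarray(scores, dtype=np.float64)
    if len(records) != len(scores):
        raise ValueError("scores must align one-to-one with records")
    high = [r for r, s in zip(records, scores) if s > cutoff]
    low = [r for r, s in zip(records, scores) if s <= cutoff]
    if not high or not low:
        warnings.warn(
            f"cutoff {cutoff:g} leaves a group empty "
            f"(high={len(high)}, low={len(low)})",
            stacklevel=2,
        )
    return high, low


def km_estimate(records: Sequence[OutcomeRecord]) -> KmCurve:
    """Product-limit survival estimate for one group.

    Subjects censored exactly at an event time are counted at risk at that
    time (the standard convention).
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one subject")
    times = np.array([r.time_months for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    return KmCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
    )


def log_rank(
    group_a: Sequence[OutcomeRecord], group_b: Sequence[OutcomeRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi², two-sided p) with 1 df."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if not any(r.event for r in group_a + group_b):
        warnings.warn("no events in either group; log-rank is uninformative", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(
        np.array([r.time_months for r in group_a]),
        np.array([r.time_months for r in group_b]),
        event_observed_A=np.array([r.event for r in group_a], dtype=int),
        event_observed_B=np.array([r.event for r in group_b], dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)
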