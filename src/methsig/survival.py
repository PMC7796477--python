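"""Kaplan-Meier estimation and two-group log-rank testing.

Thin wrappers over lifelines that expose the estimator as a plain step
function and the log-rank result as (chi2, df=1, p).  Ties use the standard
hypergeometric variance at tied event times; censoring at an event time is
counted after the event (the usual convention, and lifelines').
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) step function with risk/event counts."""

    times: np.ndarray          # sorted distinct observed times
    survival: np.ndarray       # S(t) at each time (right-continuous steps)
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if (np.diff(s) > 1e-12).any() or (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise ValueError("survival curve must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t) for arbitrary t (1 before the first observed time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    df: int = 1


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only data give S(t) = 1 everywhere.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # drop the synthetic t=0 row unless an observation actually occurs at 0
    table = kmf.event_table
    if (times > 0).all():
        table = table[table.index > 0]
    tl = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(tl).to_numpy(dtype=float)
    return SurvivalCurve(
        times=tl,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test (observed vs expected events, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    in_a = groups == levels[0]
    if in_a.all() or (~in_a).all():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        warnings.warn("no events in either group: log-rank undefined, p = 1")
        return LogRankResult(chi2=0.0, p=1.0)
    res = _ll_logrank(times[in_a], times[~in_a],
                      event_observed_A=events[in_a],
                      event_observed_B=events[~in_a])
    return LogRankResult(chi2=float(res.test_statistic), p=float(res.p_value))


def km_by_group(times, events, groups) -> dict[str, SurvivalCurve]:
    """One curve per group level."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    return {
        str(lv): km_estimate(times[groups == lv], events[groups == lv])
        for lv in pd.unique(groups)
    }


def write_curve(curve: SurvivalCurve, path) -> None:
    pd.DataFrame(
        {"time": curve.times, "survival": curve.survival,
         "at_risk": curve.at_risk, "events": curve.events}
    ).to_csv(path, sep="\t", index=False)
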