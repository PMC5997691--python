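"""Kaplan-Meier estimation and two-group log-rank comparison.

Endpoints are overall survival (OS) and progression-free survival (PFS) in
months, compared between TS-expression groups.  Estimation and testing are
delegated to lifelines; observed/expected event counts per group are
computed alongside from the standard hypergeometric risk tables.  At tied
times, events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test"]


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    """Two-group log-rank test (1 df)."""

    chi_square: float
    p_value: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
    )


def _observed_expected(times, events, group) -> tuple[np.ndarray, np.ndarray]:
    """Per-group observed and expected event counts from the risk tables."""
    obs = np.zeros(2)
    exp = np.zeros(2)
    for t in np.unique(times[events == 1]):
        at_risk = times >= t  # events precede censorings at tied times
        n_risk = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        for g in (0, 1):
            in_g = at_risk & (group == g)
            obs[g] += ((times == t) & (events == 1) & (group == g)).sum()
            exp[g] += d * in_g.sum() / n_risk
    return obs, exp


def logrank_test(times, events, group) -> LogRankResult:
    """Standard two-group log-rank test with 1-df chi-square p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    group = (group == levels[1]).astype(int)
    res = _ll_logrank(
        times[group == 0], times[group == 1],
        events[group == 0], events[group == 1],
    )
    obs, exp = _observed_expected(times, events, group)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        observed=obs,
        expected=exp,
    )
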