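"""Risk stratification from the twelve-month survival model.

The out-of-fold probability scores of one CV repetition (repetition 0 by
default) give each patient a hard survival prediction at the 0.5 threshold;
a negative prediction (predicted non-survivor) labels the patient
high-risk.  Overall survival of the low- and high-risk groups is then
compared with Kaplan-Meier product-limit curves and a two-group log-rank
test (chi-square, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .evaluate import PredictionSet
from .synth import ClinicalRecord


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(0) = 1, non-increasing step function."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class LogRankResult:
    statistic: float
    p_value: float


def stratify(
    ps: PredictionSet, repetition: int = 0, threshold: float = 0.5
) -> pd.Series:
    """Risk-group label per patient ('high' when the predicted survival
    probability falls below the threshold) from one repetition's
    out-of-fold scores."""
    if repetition >= ps.n_repetitions:
        raise ValueError(f"repetition {repetition} not available (R={ps.n_repetitions})")
    scores = ps.scores[repetition]
    if np.isnan(scores).any():
        raise ValueError("missing out-of-fold predictions for the chosen repetition")
    groups = np.where(scores < threshold, "high", "low")
    return pd.Series(groups, index=ps.patient_ids, name="risk_group")


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate (events processed before
    censorings at tied times, the standard convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tl = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(
        times=tl,
        survival=surv,
        at_risk=at_risk,
        censor_times=times[events == 0],
    )


def logrank(
    times1: np.ndarray, events1: np.ndarray, times2: np.ndarray, events2: np.ndarray
) -> LogRankResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    times1, times2 = np.asarray(times1, float), np.asarray(times2, float)
    events1, events2 = np.asarray(events1, int), np.asarray(events2, int)
    if times1.size == 0 or times2.size == 0:
        raise ValueError("both groups must be non-empty")
    if events1.sum() + events2.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(times1, times2, event_observed_A=events1, event_observed_B=events2)
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def risk_stratification(
    records: list[ClinicalRecord],
    ps: PredictionSet,
    repetition: int = 0,
    threshold: float = 0.5,
) -> dict:
    """KM curves and log-rank comparison of the model-defined risk groups.

    Returns a dict with the group labels, one SurvivalCurve per group and
    the LogRankResult.
    """
    groups = stratify(ps, repetition, threshold)
    surv = {r.patient_id: (r.os_time, r.os_event) for r in records}
    out: dict = {"groups": groups}
    tms, evs = {}, {}
    for g in ("low", "high"):
        pids = groups.index[groups == g]
        if len(pids) == 0:
            raise ValueError(
                f"risk group {g!r} is empty; the score threshold produced a single group"
            )
        tms[g] = np.array([surv[p][0] for p in pids])
        evs[g] = np.array([surv[p][1] for p in pids])
        out[f"km_{g}"] = km_estimate(tms[g], evs[g])
    out["logrank"] = logrank(tms["low"], evs["low"], tms["high"], evs["high"])
    return out
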