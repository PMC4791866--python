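"""Cluster-level genomic-instability and overall-survival statistics.

Genomic instability is the per-tumor count of called loss and gain
segments; clusters are compared with a two-sample Student t-test (pooled
variance by default, Welch by flag).  Overall survival is summarised with
the Kaplan–Meier product-limit estimator and compared across clusters
with the log-rank (Mantel–Cox) test — both the k-group omnibus test and
each group against the rest — after administrative right-censoring at a
fixed horizon (default 10 years).

The survival machinery delegates to :mod:`lifelines`; hand-computed small
instances in the test suite serve as the independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "TestResult",
    "administrative_censor",
    "instability_counts",
    "km_estimate",
    "logrank_test",
    "two_sample_t_test",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def instability_counts(segments_by_sample: dict) -> pd.DataFrame:
    """Per-sample counts of called loss/gain segments (instability profile)."""
    rows = []
    for sample, segs in segments_by_sample.items():
        n_loss = sum(1 for s in segs if s.call == "loss")
        n_gain = sum(1 for s in segs if s.call == "gain")
        rows.append(
            {"sample_id": sample, "n_losses": n_loss, "n_gains": n_gain,
             "n_total": n_loss + n_gain}
        )
    return pd.DataFrame(rows, columns=["sample_id", "n_losses", "n_gains", "n_total"])


def two_sample_t_test(a, b, pooled: bool = True) -> TestResult:
    """Two-sided two-sample Student t-test (pooled variance; Welch if not)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2 if pooled else float(len(a) + len(b) - 2)
            return TestResult(statistic=0.0, p_value=1.0, df=df)
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df))


def administrative_censor(time, event, horizon: float):
    """Right-censor every record at ``horizon`` (event beyond it -> censored)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    over = time > horizon
    return np.where(over, horizon, time), np.where(over, 0, event)


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve as a step table.

    Returns a frame with columns ``time`` and ``survival``; the curve is
    right-continuous and starts at S(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.survival_function_.reset_index()
    table.columns = ["time", "survival"]
    if table["time"].iloc[0] != 0:
        table = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), table],
            ignore_index=True,
        )
    return table


def logrank_test(
    time, event, group, horizon_years: float | None = 10.0,
    one_vs_rest: bool = True,
) -> dict:
    """Log-rank (Mantel–Cox) comparison of survival across groups.

    Applies administrative censoring at ``horizon_years`` (skipped when
    None), then computes the k-group omnibus chi-square test (k-1 df) and
    a one-vs-rest log-rank test per group.  With no events anywhere the
    statistic is 0 and p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = sorted(pd.unique(group).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if horizon_years is not None:
        time, event = administrative_censor(time, event, horizon_years)
    k = len(labels)
    if event.sum() == 0:
        null = TestResult(statistic=0.0, p_value=1.0, df=float(k - 1))
        return {
            "omnibus": null,
            "one_vs_rest": {
                g: TestResult(statistic=0.0, p_value=1.0, df=1.0) for g in labels
            },
        }
    res = multivariate_logrank_test(time, group, event)
    omnibus = TestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        df=float(k - 1),
    )
    if not one_vs_rest:
        return {"omnibus": omnibus, "one_vs_rest": {}}
    one_vs_rest = {}
    for g in labels:
        indicator = np.where(group == g, "in", "rest")
        if event.sum() == 0 or len(np.unique(indicator)) < 2:
            one_vs_rest[g] = TestResult(statistic=0.0, p_value=1.0, df=1.0)
            continue
        sub = multivariate_logrank_test(time, indicator, event)
        one_vs_rest[g] = TestResult(
            statistic=float(sub.test_statistic), p_value=float(sub.p_value), df=1.0
        )
    return {"omnibus": omnibus, "one_vs_rest": one_vs_rest}
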