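"""Kaplan-Meier estimation and log-rank comparison of subtype outcomes.

Progression-free-survival analyses exclude long-PFS outliers (time strictly
greater than 150 months by default); overall-survival analyses use all
outcome-evaluable samples. Median confidence limits use the log-log
(exponential Greenwood) transform; when the survival curve never reaches 0.5
the median is undefined and only the lower confidence limit is reported.
Censored records tied with event times are considered at risk for those
events (the standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .errors import ValidationError


@dataclass
class KMFit:
    """Product-limit fit for one group."""

    table: pd.DataFrame                 # time, survival, at_risk
    median: float | None                # None when the curve stays > 0.5
    median_ci: tuple[float | None, float | None]
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        tab = self.table[self.table["time"] <= t]
        return float(tab["survival"].iloc[-1]) if len(tab) else 1.0


@dataclass
class LogRankResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def apply_pfs_exclusion(samples: pd.DataFrame, threshold: float = 150.0,
                        time_col: str = "pfs_months",
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sample sheet into (retained, excluded) by long-PFS outliers.

    Samples with PFS time strictly greater than ``threshold`` months are
    excluded (a time of exactly ``threshold`` is retained).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    excl = samples[time_col] > threshold
    return samples[~excl].copy(), samples[excl].copy()


def km_fit(times: Sequence[float], events: Sequence[bool],
           label: str | None = None, alpha: float = 0.05) -> KMFit:
    """Kaplan-Meier product-limit fit with Greenwood-based median CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValidationError("empty group")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events, label=label or "KM")

    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    table = pd.DataFrame({"time": surv.index.to_numpy(),
                          "survival": surv.to_numpy(),
                          "at_risk": at_risk.to_numpy()})

    med = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    median = None if np.isinf(med) else float(med)
    return KMFit(
        table=table,
        median=median,
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        label=label)


def km_by_group(times: Sequence[float], events: Sequence[bool],
                groups: Sequence[str]) -> dict[str, KMFit]:
    """Per-group Kaplan-Meier fits."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=bool),
                       "group": list(groups)})
    return {g: km_fit(grp["time"], grp["event"], label=str(g))
            for g, grp in df.groupby("group", sort=True)}


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 groups: Sequence[str]) -> LogRankResult:
    """k-sample log-rank chi-square test with k-1 degrees of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("log-rank requires >= 2 groups")
    if (counts == 0).any():
        raise ValidationError("every group needs at least one observation")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(statistic=float(res.test_statistic),
                         degrees_of_freedom=len(uniq) - 1,
                         p_value=float(res.p_value))


def pfs_analysis(samples: pd.DataFrame, labels: Mapping[str, str] | None = None,
                 exclude_over: float = 150.0) -> dict:
    """Outlier exclusion, per-group KM fits, and the k-sample log-rank test.

    ``samples`` is a sample sheet with sample_id, pfs_months, pfs_event;
    ``labels`` (sample -> subtype) defaults to the sheet's subtype_label.
    """
    df = samples.dropna(subset=["pfs_months"]).copy()
    if labels is not None:
        df["group"] = df["sample_id"].map(dict(labels))
    else:
        df["group"] = df["subtype_label"]
    df = df.dropna(subset=["group"])
    retained, excluded = apply_pfs_exclusion(df, threshold=exclude_over)
    fits = km_by_group(retained["pfs_months"], retained["pfs_event"],
                       retained["group"])
    lr = logrank_test(retained["pfs_months"], retained["pfs_event"],
                      retained["group"])
    return {"fits": fits, "logrank": lr, "retained": retained,
            "excluded": excluded}
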