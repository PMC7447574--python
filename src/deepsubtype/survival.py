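"""Kaplan-Meier estimation, the two-group log-rank test, and risk-group naming.

These judge whether identified molecular subtypes separate patients by
outcome: the Kaplan-Meier product-limit curve per group, the log-rank
chi-square test between groups, and a rule that names the cluster with the
shorter survival "High risk" (label 1) and the other "Low risk" (label 0).
Estimation and testing are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

from .exceptions import ConfigurationError, DegenerateInputError, UndefinedMetricError

__all__ = [
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "assign_risk_groups",
    "RiskGroups",
    "plot_km",
]

LOW_RISK, HIGH_RISK = 0, 1


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ConfigurationError("times and events must be equal-length 1-D")
    if len(times) == 0:
        raise DegenerateInputError("need at least one subject")
    if not np.isfinite(times).all() or (times < 0).any():
        raise ConfigurationError("survival times must be finite and non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ConfigurationError("event indicators must be 0/1")
    return times, events


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve as a step table.

    Returns a frame with columns ``time`` and ``survival``, starting at
    (0, 1) and dropping only at observed event times.
    """
    times, events = _check_times(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})
    if out["time"].iloc[0] != 0.0:
        out = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), out], ignore_index=True
        )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test: chi-square(1) on observed-minus-expected events.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the statistic is
    (sum O-E)^2 / sum V. Two-sided p from chi-square with 1 df.
    """
    times, events = _check_times(times, events)
    groups = np.asarray(groups, dtype=int)
    if groups.shape != times.shape:
        raise ConfigurationError("groups must align with times")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ConfigurationError(f"log-rank needs exactly 2 groups, got {len(uniq)}")
    if events.sum() == 0:
        raise UndefinedMetricError("log-rank undefined: no events in either group")
    g1 = groups == uniq[1]
    res = _ll_logrank(times[~g1], times[g1], event_observed_A=events[~g1], event_observed_B=events[g1])
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


@dataclass
class RiskGroups:
    """Cluster-to-risk mapping plus the per-sample risk labels."""

    mapping: dict[int, int]  # cluster id -> 0 (Low) / 1 (High)
    risk: pd.Series  # per-sample risk label
    median_survival: dict[int, float]  # per cluster, NaN when undefined


def assign_risk_groups(labels, clinical: pd.DataFrame) -> RiskGroups:
    """Name the two clusters Low (0) / High (1) risk by Kaplan-Meier median.

    The cluster with the smaller median survival becomes High risk; when a
    median is undefined (curve never reaches 0.5) the restricted mean
    survival time up to the largest observed time breaks the comparison.
    Exact ties resolve to cluster index 0 = Low risk.
    """
    if isinstance(labels, pd.Series):
        lab = labels
    else:
        lab = pd.Series(np.asarray(labels, dtype=int), index=clinical.index)
    clusters = sorted(int(c) for c in lab.unique())
    if len(clusters) != 2:
        raise ConfigurationError(
            f"risk-group naming needs exactly 2 clusters, got {len(clusters)}"
        )
    horizon = float(clinical["time"].max())
    score: dict[int, float] = {}
    medians: dict[int, float] = {}
    fitted: dict[int, KaplanMeierFitter] = {}
    for c in clusters:
        sub = clinical.loc[lab[lab == c].index]
        kmf = KaplanMeierFitter().fit(sub["time"], event_observed=sub["event"])
        fitted[c] = kmf
        medians[c] = float(kmf.median_survival_time_)
    if all(np.isfinite(m) for m in medians.values()) and medians[clusters[0]] != medians[clusters[1]]:
        score = medians
    else:
        score = {
            c: float(restricted_mean_survival_time(fitted[c], t=horizon)) for c in clusters
        }
    c0, c1 = clusters
    if score[c0] < score[c1]:
        mapping = {c0: HIGH_RISK, c1: LOW_RISK}
    elif score[c1] < score[c0]:
        mapping = {c1: HIGH_RISK, c0: LOW_RISK}
    else:
        mapping = {c0: LOW_RISK, c1: HIGH_RISK}  # tie: lower cluster index = Low
    risk = lab.map(mapping).rename("risk_group")
    return RiskGroups(mapping=mapping, risk=risk, median_survival=medians)


def plot_km(clinical: pd.DataFrame, risk: pd.Series, path=None, title: str | None = None):
    """Plot Kaplan-Meier curves per risk group (green = Low risk / higher
    survival, red = High risk / lower survival)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {LOW_RISK: "green", HIGH_RISK: "red"}
    names = {LOW_RISK: "Low risk", HIGH_RISK: "High risk"}
    for g in sorted(risk.unique()):
        sub = clinical.loc[risk[risk == g].index]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=names.get(g, str(g)))
        kmf.plot_survival_function(ax=ax, color=colors.get(g, None), ci_show=False)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, metadata={"Software": None})
        plt.close(fig)
        return None
    return ax
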