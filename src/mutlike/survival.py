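"""Kaplan-Meier estimation and log-rank comparisons across subtype groups.

Conventions: at tied times, events precede censorings (the censored
subject stays in the risk set for that time's event). The median is the
smallest observed time t with S(t) <= 0.5 and is reported as NaN when
the curve never reaches 0.5. Pairwise log-rank P values are reported
raw, without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class KMCurve:
    event_times: np.ndarray  # sorted distinct times with >=1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: float  # NaN when S never reaches 0.5


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    groups: tuple[str, str] = ("1", "2")


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = tab.index.to_numpy(dtype=float)
    survival = surv.reindex(tab.index).to_numpy(dtype=float)
    below = survival <= 0.5
    median = float(event_times[below][0]) if below.any() else float("nan")
    return KMCurve(
        event_times=event_times,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
        survival=survival,
        median=median,
    )


def logrank_test(times, events, group) -> LogRankResult:
    """Two-group log-rank test; chi-square on 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    if events.sum() == 0:
        raise ValueError("no events in either group")
    a, b = group == labels[0], group == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(times[a], times[b], events[a], events[b])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        groups=(str(labels[0]), str(labels[1])),
    )


def pairwise_survival(
    ann: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "os_days",
    event_col: str = "os_event",
    diagnostic_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group KM medians plus one log-rank result per group pair.

    Returns ``(medians, pairwise)`` tables. Groups with zero samples are
    skipped. With ``diagnostic_only`` the analysis is restricted to
    diagnostic-stage samples first.
    """
    df = ann
    if diagnostic_only:
        df = df[df["disease_stage"] == "diagnostic"]
    groups = [g for g in df[group_col].unique() if (df[group_col] == g).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    order = {"MUT": 0, "MUTLIKE": 1, "WT": 2}
    groups = sorted(groups, key=lambda g: (order.get(g, 99), g))

    med_rows = []
    for g in groups:
        sub = df[df[group_col] == g]
        km = km_estimate(sub[time_col], sub[event_col])
        med_rows.append({"group": g, "n": len(sub), "median_days": km.median})
    medians = pd.DataFrame(med_rows)

    pair_rows = []
    for g1, g2 in combinations(groups, 2):
        sub = df[df[group_col].isin([g1, g2])]
        res = logrank_test(sub[time_col], sub[event_col], sub[group_col])
        pair_rows.append(
            {"group1": g1, "group2": g2, "chi_square": res.chi_square, "p": res.p_value}
        )
    return medians, pd.DataFrame(pair_rows)
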