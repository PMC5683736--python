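"""Person-years mortality rates, Kaplan-Meier estimation and the log-rank test.

These are implemented from first principles (the product-limit estimator
and the K-sample observed-vs-expected chi-square) so the outcome layer is
self-contained and can be validated against independent implementations
and a permutation null in the test suite.

Conventions: at tied times deaths precede censorings (censored subjects
remain at risk for deaths at the same time); the log-rank p-value comes
from the chi-square upper tail with K-1 degrees of freedom; crude rates
are ``1000 * deaths / person-years``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .staging import CLASSIFIABLE_STAGES

__all__ = [
    "mortality_rate",
    "kaplan_meier",
    "logrank_test",
    "LogRankResult",
    "StageOutcomeSummary",
    "stage_outcomes",
]


def _check_survival_arrays(durations, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(durations, dtype=float).ravel()
    e = np.asarray(events).ravel().astype(bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("durations and events differ in length")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("follow-up times must be finite and positive")
    return t, e


def mortality_rate(deaths: int, person_years: float) -> float:
    """Crude rate per 1,000 patient-years: ``1000 * deaths / person_years``."""
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    if not person_years > 0:
        raise ValueError("person-years must be positive")
    return 1000.0 * deaths / person_years


def kaplan_meier(durations, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table with one row at t=0 (S=1) and one per
    distinct event time: columns ``time``, ``n_at_risk``, ``n_events``,
    ``survival``.
    """
    t, e = _check_survival_arrays(durations, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times, first = np.unique(t, return_index=True)
    # deaths and total leaving at each distinct time
    d = np.array([e[(t == u)].sum() for u in times])
    n_leave = np.diff(np.append(first, t.size))
    n_at_risk = t.size - np.cumsum(np.append(0, n_leave))[:-1]
    keep = d > 0
    surv = np.cumprod(1.0 - d[keep] / n_at_risk[keep])
    out = pd.DataFrame(
        {
            "time": np.concatenate(([0.0], times[keep])),
            "n_at_risk": np.concatenate(([t.size], n_at_risk[keep])),
            "n_events": np.concatenate(([0], d[keep])),
            "survival": np.concatenate(([1.0], surv)),
        }
    )
    return out


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray = field(repr=False, default=None)
    expected: np.ndarray = field(repr=False, default=None)


def logrank_test(groups) -> LogRankResult:
    """K-sample log-rank test.

    ``groups`` is a sequence of ``(durations, events)`` pairs (K >= 2).
    The statistic is the quadratic form of observed-minus-expected event
    counts over the hypergeometric covariance at each distinct event
    time, with df = K - 1.  All-censored input is rejected (the test is
    undefined with no events).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    parsed = [_check_survival_arrays(t, e) for t, e in groups]
    K = len(parsed)
    t_all = np.concatenate([t for t, _ in parsed])
    e_all = np.concatenate([e for _, e in parsed])
    g_all = np.concatenate([np.full(t.size, k) for k, (t, _) in enumerate(parsed)])
    if not e_all.any():
        raise ValueError("log-rank test undefined: no events in any group")

    event_times = np.unique(t_all[e_all])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for u in event_times:
        at_risk = t_all >= u
        n_j = at_risk.sum()
        d_j = (e_all & (t_all == u)).sum()
        n_kj = np.bincount(g_all[at_risk], minlength=K).astype(float)
        d_kj = np.bincount(g_all[e_all & (t_all == u)], minlength=K).astype(float)
        O += d_kj
        E += d_j * n_kj / n_j
        if n_j > 1:
            frac = n_kj / n_j
            c = d_j * (n_j - d_j) / (n_j - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    x = (O - E)[:-1]
    Vr = V[:-1, :-1]
    stat = float(x @ np.linalg.pinv(Vr) @ x)
    df = K - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(_st.chi2.sf(stat, df)),
        observed=O,
        expected=E,
    )


@dataclass
class StageOutcomeSummary:
    """Per-stage outcome bookkeeping plus the group survival comparison."""

    table: pd.DataFrame
    km_curves: dict
    logrank_all_cause: LogRankResult | None
    logrank_as_related: LogRankResult | None
    total_deaths: int


def stage_outcomes(
    staged: pd.DataFrame,
    stage_col: str = "stage",
    time_col: str = "followup_years",
    event_col: str = "died",
    cause_col: str = "as_related_death",
    stages=CLASSIFIABLE_STAGES,
) -> StageOutcomeSummary:
    """Deaths, person-years, rates, KM curves and log-rank across stages.

    Only classifiable stages enter the analysis; a stage with zero
    members is reported with n = 0 and omitted from the tests.  The
    AS-related (cause-specific) analysis censors non-AS deaths.
    """
    rows = []
    km = {}
    groups_all, groups_cause = [], []
    for s in stages:
        sub = staged[staged[stage_col] == s]
        n = len(sub)
        if n == 0:
            rows.append(
                {"stage": s, "n": 0, "deaths": 0, "as_related_deaths": 0,
                 "person_years": 0.0, "rate_per_1000py": np.nan,
                 "as_rate_per_1000py": np.nan}
            )
            continue
        t = sub[time_col].to_numpy(float)
        e = sub[event_col].to_numpy().astype(bool)
        c = sub[cause_col].to_numpy().astype(bool) if cause_col in sub else np.zeros(n, bool)
        py = float(t.sum())
        rows.append(
            {
                "stage": s,
                "n": n,
                "deaths": int(e.sum()),
                "as_related_deaths": int(c.sum()),
                "person_years": py,
                "rate_per_1000py": mortality_rate(int(e.sum()), py),
                "as_rate_per_1000py": mortality_rate(int(c.sum()), py),
            }
        )
        km[s] = kaplan_meier(t, e)
        groups_all.append((t, e))
        groups_cause.append((t, e & c))

    def _safe_logrank(groups):
        if len(groups) < 2:
            return None
        try:
            return logrank_test(groups)
        except ValueError:
            return None

    table = pd.DataFrame(rows)
    return StageOutcomeSummary(
        table=table,
        km_curves=km,
        logrank_all_cause=_safe_logrank(groups_all),
        logrank_as_related=_safe_logrank(groups_cause),
        total_deaths=int(table["deaths"].sum()),
    )


def km_curves_tidy(km_curves: dict) -> pd.DataFrame:
    """Stack per-group KM tables into one tidy frame (group, time, ...)."""
    frames = []
    for g, df in km_curves.items():
        d = df.copy()
        d.insert(0, "group", g)
        frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["group", "time", "n_at_risk", "n_events", "survival"])
    return pd.concat(frames, ignore_index=True)
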