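"""Behavioural and demographic group statistics.

Per-subject summaries of the Go/NoGo task (mean RT over answered Go
trials, omission % on Go trials, false-alarm % on NoGo trials) and the
summary-statistic group tests used to characterize the samples:
pooled-variance Student t, Cohen's d, and the Pearson chi-square for a
2x2 table (no continuity correction). The identity
t = d * sqrt(n1 n2 / (n1 + n2)) links the first two.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import validate_events

__all__ = [
    "summarize_responses",
    "summarize_cohort",
    "pooled_t",
    "cohens_d",
    "chi2_2x2",
    "group_tests",
]


def summarize_responses(events: pd.DataFrame, subject_id: str = "", group: str = "") -> dict:
    """One subject's behavioural summary row.

    omission_pct = 100 * unanswered Go / Go trials; false_alarm_pct =
    100 * answered NoGo / NoGo trials; mean_rt_ms averages answered Go
    trials only (NaN if every Go trial was omitted). Requires at least
    one Go and one NoGo trial.
    """
    validate_events(events)
    types = events["trial_type"].to_numpy()
    rt = events["response_time"].to_numpy(dtype=float)
    go = types == "go"
    nogo = types == "nogo"
    if not go.any():
        raise ValueError("event table has no Go trials")
    if not nogo.any():
        raise ValueError("event table has no NoGo trials")
    answered_go = go & ~np.isnan(rt)
    return {
        "subject_id": subject_id,
        "group": group,
        "mean_rt_ms": float(np.mean(rt[answered_go])) if answered_go.any() else float("nan"),
        "omission_pct": 100.0 * float((go & np.isnan(rt)).sum()) / float(go.sum()),
        "false_alarm_pct": 100.0 * float((nogo & ~np.isnan(rt)).sum()) / float(nogo.sum()),
    }


def summarize_cohort(
    cohorts: dict[str, list[pd.DataFrame]] | list[pd.DataFrame],
    group: str = "",
) -> pd.DataFrame:
    """Stack per-subject summaries into one table.

    ``cohorts`` is either a list of event tables (one group) or a
    mapping group label -> list of event tables.
    """
    if isinstance(cohorts, list):
        cohorts = {group: cohorts}
    rows = []
    for label, tables in cohorts.items():
        for i, ev in enumerate(tables, start=1):
            rows.append(summarize_responses(ev, subject_id=f"{label}{i:02d}", group=label))
    return pd.DataFrame(rows)


def _check_summary_args(sd1: float, n1: int, sd2: float, n2: int) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("at least one group must have positive SD")


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)))


def pooled_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int]:
    """Two-sample pooled-variance Student t from summary statistics.

    Sign convention: group2 - group1 (so a slower second group gives a
    positive t). Returns ``(t, df)`` with df = n1 + n2 - 2.
    """
    _check_summary_args(sd1, n1, sd2, n2)
    sp = _pooled_sd(sd1, n1, sd2, n2)
    t = (mean2 - mean1) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    return float(t), int(n1 + n2 - 2)


def cohens_d(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Absolute standardized mean difference, |mean2 - mean1| / pooled SD."""
    _check_summary_args(sd1, n1, sd2, n2)
    sp = _pooled_sd(sd1, n1, sd2, n2)
    if sp == 0:
        raise ValueError("pooled SD is zero")
    return float(abs(mean2 - mean1) / sp)


def chi2_2x2(a, b, c, d) -> float:
    """Pearson chi-square of a 2x2 contingency table, no continuity
    correction: n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    counts = np.asarray([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m <= 0 for m in margins):
        raise ValueError("every margin of the 2x2 table must be positive")
    return float(n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float))


def group_tests(summary: pd.DataFrame, group1: str = "hc", group2: str = "ocd") -> pd.DataFrame:
    """Between-group summary-statistic tests on a cohort summary table.

    For each behavioural measure: group means/SDs, pooled Student t
    (group2 - group1), df, and Cohen's d. Measures that are constant in
    both groups (e.g. no false alarm anywhere in a tiny sample) are
    skipped — their group test is undefined.
    """
    rows = []
    for col in ("mean_rt_ms", "omission_pct", "false_alarm_pct"):
        g1 = summary.loc[summary["group"] == group1, col].dropna()
        g2 = summary.loc[summary["group"] == group2, col].dropna()
        m1, s1, n1 = g1.mean(), g1.std(ddof=1), len(g1)
        m2, s2, n2 = g2.mean(), g2.std(ddof=1), len(g2)
        if s1 == 0 and s2 == 0:
            continue
        t, df = pooled_t(m1, s1, n1, m2, s2, n2)
        rows.append(
            {
                "measure": col,
                f"{group1}_mean": m1, f"{group1}_sd": s1, f"{group1}_n": n1,
                f"{group2}_mean": m2, f"{group2}_sd": s2, f"{group2}_n": n2,
                "t": t, "df": df, "cohens_d": cohens_d(m1, s1, n1, m2, s2, n2),
            }
        )
    return pd.DataFrame(rows)
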