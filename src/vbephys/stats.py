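"""Group statistics: mean +- SEM summaries and Student's two-sample t tests
(pooled-variance by default, paired where relevant), applied metric-by-metric
to two analyzed cohorts.  No multiplicity correction is applied, matching the
reporting convention of the experimental literature this mirrors; treat the
per-row p values accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        x = np.asarray(values, float)
        x = x[np.isfinite(x)]
        if len(x) < 1:
            raise ValueError("empty group")
        sem = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        return cls(label=label, n=len(x), mean=float(np.mean(x)), sem=sem)


@dataclass
class ComparisonRow:
    metric: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    t_stat: float
    p_value: float
    paired: bool

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.05


def two_sample_t(a, b, paired: bool = False, welch: bool = False):
    """Student's two-sample t test; two-sided p.

    Unpaired tests pool the variances (classic Student) unless ``welch`` is
    set.  When both groups have zero variance the statistic is undefined and
    ``(nan, nan)`` is returned.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal lengths")
        d = a - b
        if np.all(d == d[0]) and np.var(a) == 0 and np.var(b) == 0:
            return (math.nan, math.nan)
        if np.std(d, ddof=1) == 0:
            if d[0] == 0:
                return (0.0, 1.0)
            return (math.nan, math.nan)
        res = sps.ttest_rel(a, b)
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                return (0.0, 1.0)
            return (math.nan, math.nan)
        res = sps.ttest_ind(a, b, equal_var=not welch)
    return (float(res.statistic), float(res.pvalue))


def cohort_comparison(
    results_a,
    results_b,
    metrics=None,
    labels=("A", "B"),
    paired: bool = False,
    welch: bool = False,
) -> list[ComparisonRow]:
    """One t-test row per metric across two cohorts of per-cell result dicts.

    ``results_a``/``results_b`` are sequences of ``{metric: value}`` dicts
    (e.g. from :func:`vbephys.currentclamp.threshold_metric_row`).  Every
    requested metric must be present for every cell.  Cells with NaN for a
    metric (e.g. no-burst cells) are dropped from that metric's comparison.
    """
    if metrics is None:
        metrics = list(results_a[0].keys())
    rows = []
    for m in metrics:
        try:
            va = np.array([float(r[m]) for r in results_a])
            vb = np.array([float(r[m]) for r in results_b])
        except KeyError as e:
            raise ValueError(f"metric {m!r} missing for a cell: {e}") from None
        fa, fb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        sa = GroupSummary.from_values(fa, labels[0])
        sb = GroupSummary.from_values(fb, labels[1])
        if len(fa) >= 2 and len(fb) >= 2:
            if paired and len(fa) == len(fb) == len(va):
                t, p = two_sample_t(va, vb, paired=True)
            else:
                t, p = two_sample_t(fa, fb, welch=welch)
        else:
            t, p = math.nan, math.nan
        rows.append(ComparisonRow(m, sa, sb, t, p, paired))
    return rows


def comparison_table(rows) -> pd.DataFrame:
    """Flatten comparison rows into a tidy DataFrame for reporting."""
    rec = []
    for r in rows:
        rec.append(
            {
                "metric": r.metric,
                f"{r.summary_a.label}_n": r.summary_a.n,
                f"{r.summary_a.label}_mean": r.summary_a.mean,
                f"{r.summary_a.label}_sem": r.summary_a.sem,
                f"{r.summary_b.label}_n": r.summary_b.n,
                f"{r.summary_b.label}_mean": r.summary_b.mean,
                f"{r.summary_b.label}_sem": r.summary_b.sem,
                "t": r.t_stat,
                "p": r.p_value,
                "paired": r.paired,
            }
        )
    return pd.DataFrame.from_records(rec)
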