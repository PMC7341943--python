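"""Group comparisons and figure-style significance stars.

The default test is Welch's unequal-variance t-test; Mann-Whitney U is
offered for small-n robustness.  Stars follow the usual thresholds
(* p < 0.05, ** p < 0.01, *** p < 0.001, else ns).  No multiple-testing
correction is applied by default (comparisons are reported per metric); a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometrics import MorphometryRecord

__all__ = ["GroupComparison", "compare_groups", "paired_rhizoid_contrast", "stars_for_p"]


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    test: str
    statistic: float
    p_value: float
    stars: str


def stars_for_p(p: float) -> str:
    """Pure threshold map from a two-sided p-value to significance stars."""
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(x.size))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "welch_t",
    metric: str = "",
) -> GroupComparison:
    """Two-sided comparison of two value lists.

    Descriptives are always populated; with insufficient n for the chosen
    test the p-value is NaN and the stars are "na".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    statistic = float("nan")
    p = float("nan")
    if test == "welch_t":
        if a.size >= 2 and b.size >= 2:
            res = sps.ttest_ind(a, b, equal_var=False)
            statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "mann_whitney":
        if a.size >= 1 and b.size >= 1:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()) if a.size else float("nan"),
        mean_b=float(b.mean()) if b.size else float("nan"),
        sem_a=_sem(a),
        sem_b=_sem(b),
        n_a=int(a.size),
        n_b=int(b.size),
        test=test,
        statistic=statistic,
        p_value=p,
        stars=stars_for_p(p),
    )


def paired_rhizoid_contrast(
    records_a: Iterable[MorphometryRecord],
    records_b: Iterable[MorphometryRecord],
    metrics: Sequence[str],
    test: str = "welch_t",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Compare two sets of morphometry records metric by metric.

    Returns one :class:`GroupComparison` row per requested metric.  With
    ``bh_adjust`` the p-values are Benjamini-Hochberg adjusted across the
    table before the stars are assigned.
    """
    records_a = list(records_a)
    records_b = list(records_b)
    known = MorphometryRecord.field_names()
    rows = []
    for m in metrics:
        if m not in known:
            raise ValueError(f"unknown metric {m!r}")
        va = [getattr(r, m) for r in records_a]
        vb = [getattr(r, m) for r in records_b]
        rows.append(compare_groups(va, vb, test=test, metric=m))
    if bh_adjust and rows:
        ps = np.array([r.p_value for r in rows])
        ok = np.isfinite(ps)
        if ok.any():
            adj = np.full_like(ps, np.nan)
            adj[ok] = sps.false_discovery_control(ps[ok], method="bh")
            for r, padj in zip(rows, adj):
                r.p_value = float(padj)
                r.stars = stars_for_p(r.p_value)
    return pd.DataFrame([asdict(r) for r in rows])
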