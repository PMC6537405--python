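"""Row-wise group comparisons with Holm-Šidák multiple-testing correction.

Each row (e.g. one dose level) is tested on its own with Welch's
unequal-variance two-sample t test — no pooled SD across rows — and the
family of raw p-values is adjusted by the Holm-Šidák step-down procedure at
alpha = 0.05.  Stars follow adjusted p: < 0.05 *, < 0.005 **, < 0.0005 ***.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonRow", "welch_t", "holm_sidak", "compare_rows", "stars"]

STAR_CUTOFFS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


@dataclass
class ComparisonRow:
    """One row's Welch test with family-adjusted significance."""

    label: str
    group_a_values: list[float]
    group_b_values: list[float]
    t_stat: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool

    @property
    def stars(self) -> str:
        return stars(self.p_adjusted)


def stars(p_adjusted: float) -> str:
    for cutoff, s in STAR_CUTOFFS:
        if p_adjusted < cutoff:
            return s
    return "ns"


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t test: (t, Welch-Satterthwaite df, two-sided p).

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in a group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math_inf_t(a, b)
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def math_inf_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Zero variance but different means: infinite separation, p = 0."""
    sign = 1.0 if a.mean() > b.mean() else -1.0
    return sign * np.inf, float(len(a) + len(b) - 2), 0.0


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05) -> list[tuple[float, bool]]:
    """Step-down Šidák adjustment, returned in input order.

    Sorting ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1) with a
    running maximum to keep the sequence monotone; significance follows the
    step-down stopping rule at ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return list(zip(p_adj.tolist(), reject.tolist()))


def compare_rows(
    labels: Sequence[str],
    groups_a: Sequence[Sequence[float]],
    groups_b: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """Welch test per row, Holm-Šidák correction across the family of rows."""
    if not (len(labels) == len(groups_a) == len(groups_b)):
        raise ValueError("labels and groups must align")
    raw = [welch_t(a, b) for a, b in zip(groups_a, groups_b)]
    adjusted = holm_sidak([p for _, _, p in raw], alpha=alpha)
    return [
        ComparisonRow(
            label=str(lab), group_a_values=list(map(float, a)),
            group_b_values=list(map(float, b)),
            t_stat=t, df=df, p_raw=p, p_adjusted=p_adj, significant=sig,
        )
        for lab, a, b, (t, df, p), (p_adj, sig)
        in zip(labels, groups_a, groups_b, raw, adjusted)
    ]
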