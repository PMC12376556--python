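"""Thin group-comparison statistics for the cohort reports.

These wrap scipy.stats so the report tables mirror the figure-style
annotations: group means ± SEM, a two-sided test statistic and p-value,
and a star label (ns, *, **, ***). No statistical method is re-derived
here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError


def significance_label(p: float) -> str:
    """ns (p ≥ 0.05), * (< 0.05), ** (< 0.01), *** (< 0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    significance: str

    def as_dict(self) -> dict:
        return asdict(self)


def _clean(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ParameterError(
            f"group {name!r} needs >= 2 finite values, got {arr.size}"
        )
    return arr


def group_comparison(a, b, test: str = "mann_whitney") -> ComparisonResult:
    """Two-sided comparison of two value sets.

    test: "mann_whitney" (rank-based) or "t" (unpaired two-tailed t-test).
    NaNs are dropped before testing.
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t":
        res = sps.ttest_ind(a, b)
    else:
        raise ParameterError(f"unknown test {test!r} (use 't' or 'mann_whitney')")
    p = float(res.pvalue)
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        p_value=p,
        mean_a=float(np.mean(a)),
        sem_a=float(sps.sem(a)),
        n_a=int(a.size),
        mean_b=float(np.mean(b)),
        sem_b=float(sps.sem(b)),
        n_b=int(b.size),
        significance=significance_label(p),
    )


def anova_oneway(*groups) -> dict:
    """One-way ANOVA across ≥ 2 groups (delegated to scipy)."""
    cleaned = [_clean(g, f"group{i}") for i, g in enumerate(groups)]
    if len(cleaned) < 2:
        raise ParameterError("ANOVA needs >= 2 groups")
    res = sps.f_oneway(*cleaned)
    p = float(res.pvalue)
    return {
        "test": "anova_oneway",
        "statistic": float(res.statistic),
        "p_value": p,
        "significance": significance_label(p),
        "n_groups": len(cleaned),
    }
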