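"""Two-group tests, ANOVA-based multi-group comparisons with FDR control,
and group summary tables.

The two-group test mirrors the common Prism workflow: an F test compares
variances, and the t-test uses pooled variance unless the F test rejects
at alpha = 0.05, in which case Welch's correction is applied.  Multi-group
designs run an omnibus ANOVA (one-way, two-way type-II, or Welch for
heteroscedastic groups) followed by all pairwise t-tests with
Benjamini-Hochberg adjustment across the comparison family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "two_group_test",
    "variance_f_test",
    "welch_anova",
    "anova_multi_comparisons",
    "summarize_groups",
]

VARIANCE_GATE_ALPHA = 0.05


@dataclass
class TestResult:
    comparison: str
    statistic: float
    raw_p: float
    test_name: str
    adjusted_p: float | None = None
    significant: bool | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        p = self.adjusted_p if self.adjusted_p is not None else self.raw_p
        if self.significant is None and np.isfinite(p):
            self.significant = bool(p < self.alpha)


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 2:
        raise ValueError(f"{name} needs n >= 2")
    return a


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided F test of equal variances; returns (F, p)."""
    a, b = _as_array(a, "a"), _as_array(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 0.0, 1.0
    if vb == 0 or va == 0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def two_group_test(a, b, label: str = "a vs b") -> TestResult:
    """Unpaired two-tailed t-test with an F-test variance gate.

    Pooled-variance t unless the F test rejects equal variances at
    alpha = 0.05, then Welch's correction.  Two identical zero-variance
    samples give statistic 0, p = 1.
    """
    a, b = _as_array(a, "a"), _as_array(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(label, 0.0, 1.0, "t-test (degenerate: zero variance)")
    _, p_var = variance_f_test(a, b)
    welch = p_var < VARIANCE_GATE_ALPHA
    res = sps.ttest_ind(a, b, equal_var=not welch)
    name = "Welch's t-test" if welch else "t-test (pooled variance)"
    return TestResult(label, float(res.statistic), float(res.pvalue), name)


def welch_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA; returns (F*, p).

    Standard Welch (1951) statistic with Satterthwaite-type denominator
    degrees of freedom.
    """
    ks = list(groups)
    n = np.array([len(groups[g]) for g in ks], dtype=float)
    m = np.array([np.mean(groups[g]) for g in ks])
    v = np.array([np.var(groups[g], ddof=1) for g in ks])
    if np.any(v == 0):
        raise ValueError("Welch ANOVA requires positive within-group variances")
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    k = len(ks)
    num = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = num / den
    df2 = (k**2 - 1) / (3 * lam)
    return float(f), float(sps.f.sf(f, k - 1, df2))


def _pairwise_bh(
    groups: dict[str, np.ndarray], welch: bool, alpha: float
) -> list[TestResult]:
    pairs = list(itertools.combinations(sorted(groups), 2))
    raws, stats_, names = [], [], []
    for g1, g2 in pairs:
        if welch:
            res = sps.ttest_ind(groups[g1], groups[g2], equal_var=False)
            names.append("Welch's t-test")
        else:
            res = sps.ttest_ind(groups[g1], groups[g2], equal_var=True)
            names.append("t-test (pooled variance)")
        raws.append(float(res.pvalue))
        stats_.append(float(res.statistic))
    if not pairs:
        return []
    _, adj, _, _ = multipletests(raws, alpha=alpha, method="fdr_bh")
    return [
        TestResult(f"{g1} vs {g2}", s, p, nm, adjusted_p=float(q), alpha=alpha)
        for (g1, g2), s, p, q, nm in zip(pairs, stats_, raws, adj, names, strict=True)
    ]


def anova_multi_comparisons(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    design: str = "one-way",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Omnibus ANOVA followed by BH-adjusted pairwise comparisons.

    ``design``:
      * ``"one-way"`` — classic one-way ANOVA on a dict of group samples.
      * ``"welch-brown-forsythe"`` — Welch's heteroscedastic ANOVA (for
        groups with unequal SDs), Welch pairwise t-tests.
      * ``"two-way"`` — pass a DataFrame with columns ``value``,
        ``factor_a``, ``factor_b``; type-II ANOVA via OLS, pairwise
        comparisons between the factor_a x factor_b cells.

    The first returned entry is the omnibus test; the rest are the pairwise
    comparisons with ``adjusted_p`` (BH across the family).
    """
    if design == "two-way":
        if not isinstance(groups, pd.DataFrame):
            raise ValueError("two-way design needs a DataFrame")
        need = {"value", "factor_a", "factor_b"}
        if not need <= set(groups.columns):
            raise ValueError(f"two-way design needs columns {sorted(need)}")
        cells = groups.groupby(["factor_a", "factor_b"]).size()
        full = (
            groups["factor_a"].nunique() * groups["factor_b"].nunique()
        )
        if len(cells) < full or (cells < 2).any():
            raise ValueError("two-way design has an empty or singleton cell")
        model = ols("value ~ C(factor_a) * C(factor_b)", data=groups).fit()
        tab = anova_lm(model, typ=2)
        results = [
            TestResult(
                f"two-way ANOVA: {idx}",
                float(row["F"]),
                float(row["PR(>F)"]),
                "two-way ANOVA (type II)",
                alpha=alpha,
            )
            for idx, row in tab.iterrows()
            if np.isfinite(row["F"])
        ]
        cell_groups = {
            f"{a}/{b}": sub["value"].to_numpy(float)
            for (a, b), sub in groups.groupby(["factor_a", "factor_b"])
        }
        return results + _pairwise_bh(cell_groups, welch=False, alpha=alpha)

    groups = {g: _as_array(v, g) for g, v in dict(groups).items()}
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for a multi-group design")
    if design == "one-way":
        f, p = sps.f_oneway(*groups.values())
        omni = TestResult("one-way ANOVA", float(f), float(p), "one-way ANOVA", alpha=alpha)
        pairwise = _pairwise_bh(groups, welch=False, alpha=alpha)
    elif design == "welch-brown-forsythe":
        f, p = welch_anova(groups)
        omni = TestResult("Welch ANOVA", f, p, "Brown-Forsythe/Welch ANOVA", alpha=alpha)
        pairwise = _pairwise_bh(groups, welch=True, alpha=alpha)
    else:
        raise ValueError(f"unknown design: {design!r}")
    return [omni] + pairwise


def summarize_groups(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group n, mean, SD, SEM, median, quartiles, min, max."""
    if not groups:
        raise ValueError("no groups supplied")
    rows = []
    for g, v in groups.items():
        v = np.asarray(v, dtype=float).ravel()
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows.append({
            "group_label": g,
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": sd,
            "sem": sd / np.sqrt(v.size),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
        })
    return pd.DataFrame(rows)
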