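"""Frequentist battery: factorial ANOVA, t tests, chi-square, correlations.

The ANOVA handles unbalanced designs with Type III sums of squares under
sum-to-zero factor coding (selectable); post hoc two-sample t tests are
pooled-variance with optional Bonferroni/Holm correction; the 2x2 chi-square
is Pearson's without continuity correction by default; and two Pearson
correlations are compared through Fisher's r-to-z transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "factorial_anova",
    "two_sample_t",
    "adjust_pvalues",
    "chi_square_2x2",
    "correlation_with_comparison",
]


@dataclass(frozen=True)
class TestResult:
    """A single test statistic with df, p value and per-group sizes."""

    statistic: float
    p: float
    df: float | None = None
    n: tuple | None = None
    kind: str = ""


def factorial_anova(
    table: pd.DataFrame,
    factors: list[str],
    response: str,
    ss_type: int = 3,
) -> pd.DataFrame:
    """Full-factorial ANOVA (all main effects and interactions).

    Unbalanced designs use the requested sums-of-squares type (default Type
    III with sum-to-zero coding). Effects that are inestimable because of
    empty cells are reported with NaN F and p rather than raising.

    Returns a frame indexed by effect with columns F, df_num, df_den, p.
    """
    if not factors:
        raise ValueError("at least one factor required")
    data = table.dropna(subset=[response] + list(factors)).copy()
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=data).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = sm.stats.anova_lm(model, typ=ss_type)
    aov = aov[~aov.index.isin(["Residual", "Intercept"])].copy()
    df_den = float(model.df_resid)
    out = pd.DataFrame(
        {
            "F": aov["F"].to_numpy(dtype=float),
            "df_num": aov["df"].to_numpy(dtype=float),
            "df_den": df_den,
            "p": aov["PR(>F)"].to_numpy(dtype=float),
        },
        index=[ix.replace("C(", "").replace(", Sum)", "") for ix in aov.index],
    )
    # a numerically zero residual (constant response) yields F = 0, p = 1
    if model.ssr <= 1e-12 * max(1.0, float(np.abs(data[response]).max()) ** 2):
        out["F"] = 0.0
        out["p"] = 1.0
    return out


def two_sample_t(
    x,
    y,
    correction: str = "none",
    family_size: int = 1,
) -> TestResult:
    """Pooled-variance two-sample t test, df = n1 + n2 - 2.

    ``correction`` in {none, bonferroni, holm} scales p by ``family_size``
    (for a single test from a family, Holm's step-down reduces to the
    Bonferroni bound; use :func:`adjust_pvalues` to correct a whole family
    jointly). With zero variance in both groups the statistic is 0 for equal
    means and signed infinity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if correction not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * sps.t.sf(abs(t), df)
    if correction != "none":
        p = min(1.0, p * family_size)
    return TestResult(statistic=float(t), p=float(p), df=float(df), n=(n1, n2), kind="t")


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Adjust a family of p values (``holm`` or ``bonferroni``)."""
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (df = 1).

    Continuity correction off by default. Raises on a zero marginal.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(t, correction=correction)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue), df=1.0,
        n=tuple(int(v) for v in t.sum(axis=1)), kind="chi2",
    )


def _pearson(pairs) -> TestResult:
    a = np.asarray(pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 4:
        raise ValueError("need >= 4 (x, y) pairs")
    if np.ptp(a[:, 0]) == 0 or np.ptp(a[:, 1]) == 0:
        raise ValueError("constant series: correlation undefined")
    r, p = sps.pearsonr(a[:, 0], a[:, 1])
    return TestResult(statistic=float(r), p=float(p), df=float(len(a) - 2), n=(len(a),), kind="r")


def correlation_with_comparison(pairs_a, pairs_b) -> dict:
    """Pearson r per group plus a Fisher r-to-z comparison of the two.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    ra = _pearson(pairs_a)
    rb = _pearson(pairs_b)
    n1, n2 = ra.n[0], rb.n[0]
    z = (np.arctanh(ra.statistic) - np.arctanh(rb.statistic)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    pz = 2.0 * sps.norm.sf(abs(z))
    return {
        "group_a": ra,
        "group_b": rb,
        "fisher_z": TestResult(statistic=float(z), p=float(pz), n=(n1, n2), kind="z"),
    }
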