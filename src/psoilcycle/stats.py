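"""Univariate inference: two-way ANOVA, assumption checks, Spearman
correlation and multiplicity adjustments."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "two_way_anova",
    "assumption_checks",
    "bonferroni",
    "bh_fdr",
    "spearman",
]


@dataclass
class AnovaTerm:
    name: str
    ss: float
    df: int
    F: float
    p: float
    p_bonferroni: float


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus residual info and assumption-check p-values."""

    terms: dict[str, AnovaTerm]
    residual_ss: float
    residual_df: int
    shapiro_p: float | None
    levene_p: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms.values()],
                "ss": [t.ss for t in self.terms.values()],
                "df": [t.df for t in self.terms.values()],
                "F": [t.F for t in self.terms.values()],
                "p": [t.p for t in self.terms.values()],
                "p_bonferroni": [t.p_bonferroni for t in self.terms.values()],
            }
        )


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def two_way_anova(
    y,
    factor_a,
    factor_b=None,
    *,
    family_size: int = 1,
    check_assumptions: bool = True,
) -> AnovaResult:
    """Two-way (or one-way) fixed-effects ANOVA with Type-II sums of squares.

    ``factor_a`` is the nutrient-input flag, ``factor_b`` the site; with
    ``factor_b=None`` the routine degrades to one-way ANOVA. Term p-values
    are Bonferroni-adjusted for ``family_size`` simultaneous features.
    """
    y = np.asarray(y, dtype=float)
    degenerate = np.ptp(y) == 0  # constant response: every term SS is exactly 0
    a = pd.Categorical(np.asarray(factor_a))
    if len(a.categories) < 2:
        raise ValueError("factor_a needs at least 2 levels")
    df = pd.DataFrame({"y": y, "A": a})
    formula = "y ~ C(A)"
    terms_map = {"input": "C(A)"}
    if factor_b is not None:
        b = pd.Categorical(np.asarray(factor_b))
        if len(b.categories) < 2:
            raise ValueError("factor_b needs at least 2 levels")
        df["B"] = b
        # interaction requires every cell occupied
        cells = df.groupby(["A", "B"], observed=False).size()
        if (cells == 0).any():
            raise ValueError("empty design cell; cannot estimate interaction")
        formula = "y ~ C(A) + C(B) + C(A):C(B)"
        terms_map = {"input": "C(A)", "site": "C(B)", "input:site": "C(A):C(B)"}
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=2)
    terms: dict[str, AnovaTerm] = {}
    for name, sm_name in terms_map.items():
        row = table.loc[sm_name]
        p = float(row["PR(>F)"])
        f = float(row["F"])
        if degenerate or not np.isfinite(f):
            f, p = 0.0, 1.0
        terms[name] = AnovaTerm(
            name=name,
            ss=0.0 if degenerate else float(row["sum_sq"]),
            df=int(row["df"]),
            F=f,
            p=p,
            p_bonferroni=min(1.0, p * family_size),
        )
    shapiro_p = levene_p = None
    if check_assumptions:
        group_key = df["A"].astype(str)
        if factor_b is not None:
            group_key = group_key + "/" + df["B"].astype(str)
        shapiro_p, levene_p = assumption_checks(fit.resid.to_numpy(), group_key)
    return AnovaResult(
        terms=terms,
        residual_ss=float(table.loc["Residual", "sum_sq"]),
        residual_df=int(table.loc["Residual", "df"]),
        shapiro_p=shapiro_p,
        levene_p=levene_p,
    )


def assumption_checks(residuals, groups) -> tuple[float | None, float | None]:
    """Shapiro–Wilk normality p on residuals and Levene variance-homogeneity
    p across groups. Degenerate inputs yield ``None`` with a warning; p-values
    below 0.05 are logged but never abort the pipeline."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError("need at least 3 residuals")
    groups = pd.Series(np.asarray(groups))
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(residuals) == 0:
        logger.warning("constant residuals: normality test undefined")
        return None, None
    shapiro_p = float(scipy.stats.shapiro(residuals).pvalue)
    by_group = [residuals[groups.to_numpy() == g] for g in groups.unique()]
    by_group = [g for g in by_group if g.size > 0]
    levene_p = float(scipy.stats.levene(*by_group).pvalue)
    if shapiro_p < 0.05:
        logger.warning("residual normality rejected (Shapiro p=%.3g)", shapiro_p)
    if levene_p < 0.05:
        logger.warning("variance homogeneity rejected (Levene p=%.3g)", levene_p)
    return shapiro_p, levene_p


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` with m the family size."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    res = scipy.stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=x.size)
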