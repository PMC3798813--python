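"""Statistical battery for the validation benches.

Paired and unpaired comparisons, Pearson correlation, fixed-effects
factorial ANOVA and model II regression. Model II is the reduced major axis
(geometric mean) estimate — slope ``sign(r) sd(y)/sd(x)`` — appropriate when
both variables carry comparable measurement error, as with two tracking
conditions of the same motion. All tests are two-sided with a default 5%
significance level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "model2_regression",
    "paired_t",
    "wilcoxon_signed_rank",
    "pearson",
    "factorial_anova",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def model2_regression(x, y) -> RegressionResult:
    """Reduced major axis regression.

    ``slope = sign(r) sd(y)/sd(x)``, intercept through the means. Unlike
    ordinary least squares the slope is not attenuated by noise in ``x``
    when both variables carry similar error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in x or y: slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RegressionResult(slope=float(slope), intercept=intercept, r2=r * r, n=x.size)


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; (t, p).

    Identical samples give (0, 1); a constant non-zero difference (zero
    variance) is rejected as undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("paired samples of equal length n >= 3 required")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValidationError("differences have zero variance: t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; (W, p). All-zero differences
    return trivially (W=0, p=1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("paired samples of equal length n >= 3 required")
    if np.all(a == b):
        return 0.0, 1.0
    w, p = sps.wilcoxon(a, b)
    return float(w), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("paired samples of equal length n >= 3 required")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AnovaResult:
    """Per-factor F statistics of a fixed-effects factorial model."""

    table: pd.DataFrame  # index: factor name; columns: F, p, df

    def f(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: bool | str = "auto",
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with main effects (and interactions when
    replicates exist).

    Every cell of the full factorial design must be non-empty; with one
    observation per cell only main effects are estimable, so
    ``interactions='auto'`` includes interaction terms only when some cell
    holds replicates. Degenerate effects (zero sum of squares in a constant
    response) report F = 0, p = 1.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = data[[response] + factors].copy().rename(columns={response: "_y"})
    counts = df.groupby(factors, observed=True).size()
    levels = [df[f].unique() for f in factors]
    missing = [
        combo
        for combo in itertools.product(*levels)
        if (combo if len(combo) > 1 else combo[0]) not in counts.index
    ]
    if missing:
        raise ValidationError(f"empty design cells: {missing[:10]}")
    if interactions == "auto":
        interactions = bool((counts > 1).any())
    joiner = " * " if (interactions and len(factors) > 1) else " + "
    formula = "_y ~ " + joiner.join(f"C({f})" for f in factors)
    response_var = float(np.var(df["_y"].to_numpy()))
    fit = ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    tab = tab.rename(
        index=lambda s: s.replace("C(", "").replace(")", "").replace(":", " x ")
    )
    out = pd.DataFrame(
        {
            "F": tab["F"],
            "p": tab["PR(>F)"],
            "df": tab["df"],
            "sum_sq": tab["sum_sq"],
        }
    ).drop(index="Residual", errors="ignore")
    # a constant response has no estimable effects: report F=0, p=1 rather
    # than the numerical fuzz an OLS fit of an all-equal vector produces
    mean_sq = float(np.mean(df["_y"].to_numpy())) ** 2
    if response_var <= 1e-18 * (1.0 + mean_sq):
        out["F"] = 0.0
        out["p"] = 1.0
    out["p"] = out["p"].fillna(1.0)
    out["F"] = out["F"].fillna(0.0)
    return AnovaResult(table=out)
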