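"""Predicting navigation error from task scores: composites, robust
regressions and the descriptive tests.

The confirmatory analysis averages z-scores over predefined task
categories (one side of each design dimension) and regresses the mean
navigation distance-error ratio on each composite separately; the
exploratory analysis does the same with the factor scores of each geomin
rotation set.  "Robust regression" is OLS with a heteroscedasticity-
consistent (HC3 sandwich) standard error and a 1-df Wald chi-square; a
Huber M-estimation variant is available since different software hides
different estimators behind that name.  Family-wise error is controlled
with Šidák-corrected levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "CATEGORY_TREE",
    "RegressionResult",
    "WhiteTestResult",
    "build_category_composites",
    "robust_regression",
    "white_test",
    "sidak_threshold",
    "one_sample_t",
    "pearson_with_critical",
    "critical_correlation",
    "rm_anova_gg",
    "paired_contrast",
    "confirmatory_analysis",
    "exploratory_analysis",
]


CATEGORY_TREE: dict[str, tuple[str, ...]] = {
    "egocentric": ("ROT", "MOV", "RFM", "MFM", "CHA"),
    "allocentric": ("RWM", "MWM", "CWM"),
    "distance": ("MOV", "MWM", "MFM"),
    "direction": ("ROT", "RWM", "RFM"),
    "perceived": ("ROT", "MOV", "RWM", "MWM", "CHA", "CWM"),
    "remembered": ("RFM", "MFM"),
    "static": ("ROT", "MOV", "RWM", "MWM", "RFM", "MFM"),
    "dynamic": ("CHA", "CWM"),
}
"""Category membership from the task classification tree.

The chase tasks combine distance and direction judgements and therefore
belong to neither single-judgement composite."""


@dataclass(frozen=True)
class WhiteTestResult:
    aux_r2: float
    statistic: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """Slope, robust SE and Wald test for one predictor of navigation error."""

    predictor: str
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    n: int
    white: WhiteTestResult | None = None
    method: str = "hc3"

    def __post_init__(self) -> None:
        if self.se > 0 and not math.isclose(
            self.wald_chi2, (self.beta / self.se) ** 2, rel_tol=1e-8
        ):
            raise ValueError("Wald statistic must equal (beta/se)^2")


def build_category_composites(
    z_matrix: pd.DataFrame, tree: dict[str, tuple[str, ...]] = CATEGORY_TREE
) -> pd.DataFrame:
    """Per-participant mean z over the member tasks of each category."""
    unknown = {t for members in tree.values() for t in members} - set(z_matrix.columns)
    if unknown:
        raise ValueError(f"unknown task code(s) {sorted(unknown)} in category tree")
    return pd.DataFrame(
        {name: z_matrix[list(members)].mean(axis=1) for name, members in tree.items()},
        index=z_matrix.index,
    )


def white_test(x: np.ndarray, y: np.ndarray) -> WhiteTestResult:
    """White's heteroscedasticity test for a single-predictor regression.

    Squared OLS residuals are regressed on {x, x^2}; the statistic is
    n * r^2 of that auxiliary regression, chi-square with 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n <= 3:
        raise ValueError("White's test needs n > 3")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    e2 = resid**2
    if np.allclose(e2, 0.0, atol=1e-24) or np.ptp(e2) < 1e-24:
        raise ValueError("degenerate fit: residuals carry no variance to test")
    aux = sm.OLS(e2, sm.add_constant(np.column_stack([x, x**2]))).fit()
    stat = n * aux.rsquared
    return WhiteTestResult(
        aux_r2=float(aux.rsquared),
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=2)),
    )


def robust_regression(
    x: np.ndarray,
    y: np.ndarray,
    predictor: str = "x",
    method: str = "hc3",
    run_white: bool = True,
) -> RegressionResult:
    """Regress navigation error on one predictor with a robust Wald test.

    method="hc3": OLS slope with the HC3 sandwich covariance.
    method="huber": Huber M-estimation (robust to outlying responses).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x, y with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    X = sm.add_constant(x)
    if method == "hc3":
        fit = sm.OLS(y, X).fit(cov_type="HC3")
    elif method == "huber":
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    chi2 = (beta / se) ** 2
    white = None
    if run_white:
        try:
            white = white_test(x, y)
        except ValueError:
            white = None
    return RegressionResult(
        predictor=predictor,
        beta=beta,
        se=se,
        wald_chi2=chi2,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        n=len(x),
        white=white,
        method=method,
    )


def sidak_threshold(alpha: float, k: int) -> float:
    """Šidák-corrected per-test level: 1 - (1 - alpha)^(1/k)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


@dataclass(frozen=True)
class OneSampleT:
    t: float
    df: int
    se: float
    p_value: float
    cohen_d: float


def one_sample_t(values: np.ndarray, mu0: float) -> OneSampleT:
    """Two-tailed one-sample t-test with Cohen's d = t / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(v, mu0)
    return OneSampleT(
        t=float(res.statistic),
        df=n - 1,
        se=float(sd / math.sqrt(n)),
        p_value=float(res.pvalue),
        cohen_d=float(res.statistic / math.sqrt(n)),
    )


def critical_correlation(alpha: float, df: int) -> float:
    """|r| beyond which a Pearson correlation is significant at level alpha
    (two-tailed) with the given degrees of freedom."""
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(math.sqrt(t**2 / (t**2 + df)))


def pearson_with_critical(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05, df: int | None = None
) -> tuple[float, float, float]:
    """Pearson r, its two-tailed p, and the critical |r| at level alpha.

    ``df`` defaults to n (the convention that reproduces the reported
    critical value when the subscript denotes sample size); pass n - 2 for
    the textbook residual degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    if df is None:
        df = len(x)
    return float(r), float(p), critical_correlation(alpha, df)


def rm_anova_gg(matrix: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is participants x levels (complete data).  Returns F, the
    GG epsilon, corrected dfs and the corrected p-value, plus the effect
    mean square error.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 3:
        raise ValueError("need >= 3 participants and >= 2 levels")
    if not np.all(np.isfinite(M)):
        raise ValueError("missing cells in repeated-measures matrix")
    n, k = M.shape
    grand = M.mean()
    subj = M.mean(axis=1)
    cond = M.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_err = np.sum((M - subj[:, None] - cond[None, :] + grand) ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err == 0:  # no subject-by-condition variability left
        F = 0.0 if np.isclose(ss_cond, 0.0) else np.inf
    else:
        F = (ss_cond / df1) / ms_err
    S = np.cov(M, rowvar=False)
    C = np.eye(k) - 1.0 / k
    V = C @ S @ C
    w = np.linalg.eigvalsh(V)
    sw2 = float(np.sum(w**2))
    eps = 1.0 if sw2 == 0 else float(np.sum(w) ** 2 / (df1 * sw2))
    eps = min(1.0, max(eps, 1.0 / df1))
    p = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    return {
        "F": float(F),
        "df1": eps * df1,
        "df2": eps * df2,
        "epsilon": eps,
        "p_value": p,
        "mse": float(ms_err),
    }


def paired_contrast(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired contrast as F (= squared paired t) with Cohen's d for
    dependent samples (mean difference / SD of differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    t = d.mean() / (sd / math.sqrt(n))
    return {
        "F": float(t**2),
        "df1": 1,
        "df2": n - 1,
        "p_value": float(stats.f.sf(t**2, 1, n - 1)),
        "cohen_d": float(d.mean() / sd),
        "mse": float(sd**2 / 2.0),
    }


# ---------------------------------------------------------------------------
# study-level analyses


def confirmatory_analysis(
    z_matrix: pd.DataFrame,
    nav_error: pd.Series | np.ndarray,
    alpha: float = 0.05,
    method: str = "hc3",
    tree: dict[str, tuple[str, ...]] = CATEGORY_TREE,
) -> pd.DataFrame:
    """Robust regressions of navigation error on each category composite.

    Returns a table (type, factor, chi2, beta, p_value, significant) with
    the Šidák flag computed over the family of all composites.
    """
    comps = build_category_composites(z_matrix, tree)
    y = np.asarray(nav_error, dtype=float)
    level = sidak_threshold(alpha, len(comps.columns))
    rows = []
    for name in comps.columns:
        res = robust_regression(comps[name].to_numpy(), y, predictor=name, method=method)
        rows.append(
            {
                "type": "confirmatory",
                "factor": name,
                "chi2": res.wald_chi2,
                "beta": res.beta,
                "p_value": res.p_value,
                "white_p": res.white.p_value if res.white else np.nan,
                "significant": res.p_value < level,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["sidak_level"] = level
    return out


def exploratory_analysis(
    refa_results,
    nav_error: pd.Series | np.ndarray,
    alpha: float = 0.05,
    method: str = "hc3",
) -> pd.DataFrame:
    """Robust regressions of navigation error on every factor of every
    geomin rotation set; the Šidák family is the factors of one set."""
    y = np.asarray(nav_error, dtype=float)
    m = refa_results.n_factors
    level = sidak_threshold(alpha, m)
    rows = []
    n_sets = len(refa_results.rotation_sets) if refa_results.rotation_sets else 1
    for s in range(n_sets):
        scores = refa_results.factor_scores(s if refa_results.rotation_sets else None)
        for j in range(m):
            name = f"Set {s + 1} F{j + 1}"
            res = robust_regression(scores[:, j], y, predictor=name, method=method)
            rows.append(
                {
                    "type": "exploratory",
                    "factor": name,
                    "chi2": res.wald_chi2,
                    "beta": res.beta,
                    "p_value": res.p_value,
                    "white_p": res.white.p_value if res.white else np.nan,
                    "significant": res.p_value < level,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["sidak_level"] = level
    return out
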