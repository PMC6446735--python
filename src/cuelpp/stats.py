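"""Validation contrasts and outcome statistics.

Covers the quadratic arousal-trend contrast, the two-group multivariate
(Hotelling T²) tests on the 8-category LPP profile, Bonferroni-corrected
pairwise comparisons, a tie-aware Mann–Whitney U test with exact small-sample
enumeration, a quasi-Poisson GLM (Poisson log-link with Pearson dispersion)
for candy counts, and covariate balance checks. All p-values are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import CATEGORIES
from .data_model import ValidationError

HIGH_AROUSAL = ("erotica", "mutilation")
MID_AROUSAL = ("romantic", "violence")
LOW_AROUSAL = ("neutral", "pollution")


@dataclass
class TestResult:
    """One statistical test: statistic, df, p-values and an effect summary."""

    name: str
    stat_name: str
    statistic: float
    df: Tuple[float, ...] | float
    p_raw: float
    p_adjusted: Optional[float] = None
    adjustment: str = "none"
    effect: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 or np.isnan(self.p_raw)):
            raise ValidationError("p value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValidationError("adjusted p cannot be below raw p")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stat_name": self.stat_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "adjustment": self.adjustment,
            "effect": self.effect,
            "ci": self.ci,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# quadratic arousal trend
# ---------------------------------------------------------------------------

def arousal_contrast(lpp_df: pd.DataFrame) -> np.ndarray:
    """Per-participant quadratic contrast over the 3 nonfood arousal levels.

    high = mean(erotica, mutilation), mid = mean(romantic, violence),
    low = mean(neutral, pollution); c = high − 2·mid + low.
    """
    def level(cats):
        return lpp_df[[f"lpp_{c}" for c in cats]].to_numpy(dtype=float).mean(axis=1)

    return level(HIGH_AROUSAL) - 2.0 * level(MID_AROUSAL) + level(LOW_AROUSAL)


def quadratic_trend_test(lpp_df: pd.DataFrame, members: Sequence) -> TestResult:
    """One-sample t test of the quadratic arousal contrast within a group."""
    sub = lpp_df.loc[list(members)]
    if len(sub) < 2:
        raise ValidationError("quadratic trend test needs a group of size >= 2")
    c = arousal_contrast(sub)
    if np.allclose(c, 0.0):
        return TestResult(
            "quadratic_trend", "t", 0.0, len(c) - 1, 1.0, effect=0.0
        )
    t, p = sps.ttest_1samp(c, 0.0)
    return TestResult(
        "quadratic_trend", "t", float(t), len(c) - 1, float(p),
        effect=float(c.mean()),
    )


# ---------------------------------------------------------------------------
# multivariate group x category tests
# ---------------------------------------------------------------------------

def hotelling_two_sample(X1: np.ndarray, X2: np.ndarray, name: str) -> TestResult:
    """Two-group Hotelling T² with its exact F conversion."""
    X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
    n1, n2 = X1.shape[0], X2.shape[0]
    p = X1.shape[1]
    n = n1 + n2
    if n - 2 < p:
        raise ValidationError("rank-deficient: need n1 + n2 - 2 >= dimensions")
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S = ((n1 - 1) * np.cov(X1, rowvar=False, ddof=1)
         + (n2 - 1) * np.cov(X2, rowvar=False, ddof=1)) / (n - 2)
    S = np.atleast_2d(S)
    t2 = float(n1 * n2 / n * d @ np.linalg.solve(S, d))
    f = (n - p - 1) / ((n - 2) * p) * t2
    p_raw = float(sps.f.sf(f, p, n - p - 1))
    return TestResult(name, "T2", t2, (p, n - p - 1), p_raw, note=f"F={f:.6g}")


def _difference_contrasts(m: int) -> np.ndarray:
    """Orthonormal (Helmert) contrast matrix, (m−1) x m, rows orthonormal and
    orthogonal to the constant vector."""
    C = np.zeros((m - 1, m))
    for i in range(1, m):
        C[i - 1, :i] = 1.0 / i
        C[i - 1, i] = -1.0
        C[i - 1] /= np.linalg.norm(C[i - 1])
    return C


def _mlm_hotelling(Y: np.ndarray, x: np.ndarray, which: int, name: str) -> TestResult:
    """Hotelling T² for one coefficient row of the multivariate linear model
    Y = X B + E with X = [1, x]."""
    n, q = Y.shape
    X = np.column_stack([np.ones(n), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    E = Y - X @ B
    nu = n - X.shape[1]
    if nu < q:
        raise ValidationError("rank-deficient: need residual df >= dimensions")
    S = E.T @ E / nu
    b = B[which]
    t2 = float(b @ np.linalg.solve(S, b) / XtX_inv[which, which])
    f = (nu - q + 1) / (nu * q) * t2
    p_raw = float(sps.f.sf(f, q, nu - q + 1))
    return TestResult(name, "T2", t2, (q, nu - q + 1), p_raw, note=f"F={f:.6g}")


def group_by_category_test(
    lpp_matrix: np.ndarray,
    groups: Sequence,
) -> Dict[str, TestResult]:
    """Multivariate tests on the 8-category LPP profiles of two groups.

    Returns the between-group test on the raw 8-vector (two-group Hotelling
    T²), and the within-subject category effect and group x category
    interaction tested on 7 orthonormal difference contrasts via a
    two-column (intercept + centred group) multivariate linear model. T² is
    invariant to the choice of orthonormal contrast basis.
    """
    X = np.asarray(lpp_matrix, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError("exactly two groups required")
    m1, m2 = X[g == levels[0]], X[g == levels[1]]
    between = hotelling_two_sample(m1, m2, "group")

    C = _difference_contrasts(X.shape[1])
    Yc = X @ C.T
    x = np.where(g == levels[0], 0.5, -0.5)     # centred two-level coding
    x = x - x.mean()
    category = _mlm_hotelling(Yc, x, which=0, name="category")
    interaction = _mlm_hotelling(Yc, x, which=1, name="interaction")
    return {"group": between, "category": category, "interaction": interaction}


def pairwise_bonferroni(p_values: Sequence[float], family_size: int) -> List[float]:
    """Bonferroni adjustment: p_adj = min(1, m·p)."""
    if family_size < len(p_values):
        raise ValidationError("family size must be >= number of tests")
    return [min(1.0, family_size * float(p)) for p in p_values]


def pairwise_group_comparisons(
    lpp_df: pd.DataFrame,
    labels: Mapping,
    family_size: int = len(CATEGORIES),
) -> List[TestResult]:
    """Between-group t test per category, Bonferroni-corrected."""
    pids = list(lpp_df.index)
    g = np.asarray([labels[p] for p in pids])
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError("exactly two groups required")
    results = []
    raw = []
    for cat in CATEGORIES:
        x1 = lpp_df.loc[g == levels[0], f"lpp_{cat}"].to_numpy(dtype=float)
        x2 = lpp_df.loc[g == levels[1], f"lpp_{cat}"].to_numpy(dtype=float)
        t, p = sps.ttest_ind(x1, x2)
        raw.append(float(p))
        results.append(
            TestResult(
                f"between_{cat}", "t", float(t), len(x1) + len(x2) - 2, float(p),
                effect=float(x1.mean() - x2.mean()),
            )
        )
    for r, p_adj in zip(results, pairwise_bonferroni(raw, family_size)):
        r.p_adjusted = p_adj
        r.adjustment = "bonferroni"
    return results


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 200_000


def _u_from_ranks(rank_sum_x: float, n1: int) -> float:
    return rank_sum_x - n1 * (n1 + 1) / 2.0


@dataclass
class MannWhitneyResult(TestResult):
    u_x: float = 0.0
    u_y: float = 0.0
    method: str = "normal"


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Mann–Whitney U with midranks for ties.

    ``method='exact'`` enumerates all C(n1+n2, n1) group labelings of the
    pooled midranks (used automatically when that count is at most 200,000);
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction is used. The reported statistic follows the
    min(U_x, U_y) convention; p is two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = _u_from_ranks(ranks[:n1].sum(), n1)
    u_y = n1 * n2 - u_x
    u_min = min(u_x, u_y)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        return MannWhitneyResult(
            "mann_whitney", "U", u_min, float(n1 + n2 - 2), 1.0,
            u_x=u_x, u_y=u_y, method="degenerate",
        )

    n_comb = math.comb(n1 + n2, n1)
    if method == "auto":
        method = "exact" if n_comb <= EXACT_ENUMERATION_LIMIT else "normal"

    if method == "exact":
        if n_comb > EXACT_ENUMERATION_LIMIT:
            raise ValidationError(
                f"exact enumeration over {n_comb} labelings exceeds the limit"
            )
        dev_obs = abs(u_x - mu) - 1e-12
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs:
                hits += 1
        p = hits / n_comb
    elif method == "normal":
        N = n1 + n2
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(t_counts ** 3 - t_counts) / (N * (N - 1.0))
        var = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_x - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
    else:
        raise ValidationError("method must be 'auto', 'exact' or 'normal'")

    return MannWhitneyResult(
        "mann_whitney", "U", float(u_min), float(n1 + n2 - 2), float(p),
        u_x=float(u_x), u_y=float(u_y), method=method,
    )


# ---------------------------------------------------------------------------
# quasi-Poisson GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Quasi-Poisson fit: log-scale coefficients, Pearson dispersion, and
    exponentiated rate ratios with Wald 95% CIs."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    dispersion: float
    rate_ratio: pd.Series
    conf_int: pd.DataFrame          # columns lo, hi on the rate-ratio scale
    fitted_means: np.ndarray
    p_values: pd.Series
    converged: bool
    n_obs: int

    def wald_test(self, term: str) -> TestResult:
        z = float(self.coefficients[term] / np.sqrt(self.covariance.loc[term, term]))
        return TestResult(
            f"glm_{term}", "z", z, np.inf, float(self.p_values[term]),
            effect=float(self.rate_ratio[term]),
            ci=(float(self.conf_int.loc[term, "lo"]),
                float(self.conf_int.loc[term, "hi"])),
        )


def _encode_design(design: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode non-numeric columns (first level dropped)."""
    parts = []
    for col in design.columns:
        s = design[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float).rename(col))
        else:
            levels = sorted(map(str, set(s)))
            for lev in levels[1:]:
                parts.append((s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]"))
    return pd.concat(parts, axis=1)


def quasipoisson_fit(counts, design: pd.DataFrame) -> GLMFit:
    """Quasi-Poisson GLM: Poisson log-link IRLS, dispersion from Pearson X².

    ``design`` holds the predictors (an intercept is added; categorical
    columns are one-hot encoded). Coefficient covariance is
    phi * (X' W X)^-1 and 95% CIs are Wald intervals on the log scale,
    exponentiated to rate ratios.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValidationError("counts must be non-negative")
    Xdf = _encode_design(design.reset_index(drop=True))
    Xdf.insert(0, "intercept", 1.0)
    X = Xdf.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is not full rank")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"quasi-Poisson IRLS did not converge in {res.fit_history['iteration']} iterations"
        )
    names = list(Xdf.columns)
    coef = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    se = np.sqrt(np.diag(cov))
    zcrit = sps.norm.ppf(0.975)
    ci = pd.DataFrame(
        {
            "lo": np.exp(coef.to_numpy() - zcrit * se),
            "hi": np.exp(coef.to_numpy() + zcrit * se),
        },
        index=names,
    )
    z = coef.to_numpy() / se
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=names)
    if np.any(~np.isfinite(se)) or np.any(se > 1e3):
        warnings.warn("separation suspected: some Wald CIs are diverging")
    return GLMFit(
        coefficients=coef,
        covariance=cov,
        dispersion=float(res.scale),
        rate_ratio=pd.Series(np.exp(coef.to_numpy()), index=names),
        conf_int=ci,
        fitted_means=np.asarray(res.mu),
        p_values=pvals,
        converged=bool(res.converged),
        n_obs=int(y.size),
    )


# ---------------------------------------------------------------------------
# covariate balance
# ---------------------------------------------------------------------------

def covariate_balance(
    covariates: pd.DataFrame,
    labels: Mapping,
) -> List[TestResult]:
    """Per-covariate two-group comparison: t test for numeric columns,
    chi-square (no continuity correction) for categoricals."""
    pids = list(covariates.index)
    g = np.asarray([labels[p] for p in pids])
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError("exactly two groups required")
    results = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc":
            x1 = s[g == levels[0]].to_numpy(dtype=float)
            x2 = s[g == levels[1]].to_numpy(dtype=float)
            if np.var(np.concatenate([x1, x2])) == 0:
                results.append(
                    TestResult(col, "t", np.nan, np.nan, np.nan,
                               note="zero variance: not testable")
                )
                continue
            t, p = sps.ttest_ind(x1, x2)
            results.append(
                TestResult(col, "t", float(t), len(pids) - 2, float(p),
                           effect=float(x1.mean() - x2.mean()))
            )
        else:
            table = pd.crosstab(s.astype(str), g)
            if table.shape[0] < 2:
                results.append(
                    TestResult(col, "chi2", np.nan, np.nan, np.nan,
                               note="single level: not testable")
                )
                continue
            chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
            results.append(TestResult(col, "chi2", float(chi2), float(df), float(p)))
    return results


def one_sample_t(values, popmean: float = 0.0, name: str = "one_sample_t") -> TestResult:
    """One-sample t test (used for SLIM-vs-anchor satiety checks)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.allclose(x, popmean):
        return TestResult(name, "t", 0.0, x.size - 1, 1.0, effect=0.0)
    t, p = sps.ttest_1samp(x, popmean)
    return TestResult(name, "t", float(t), x.size - 1, float(p),
                      effect=float(x.mean() - popmean))
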