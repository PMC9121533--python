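"""Group comparisons, adjusted correlations, stratified FDR, and cognition models.

The statistical stage mirrors a normality-gated design: Shapiro-Wilk decides
between Student's t-test and Mann-Whitney U per feature (assessed per group;
the nonparametric branch is taken if either group rejects), non-normal
variables are log-transformed before parametric use, hemodynamic features are
age- and sex-adjusted by OLS residualisation before correlation analyses, and
Benjamini-Hochberg FDR is applied independently within each (group x
parameter-map family) stratum. Cognition models are ordinary least squares
with pre-selected covariates, reported with unstandardised b, standardised
beta, 95% CI, p and partial correlation per predictor, gated on an
unadjusted univariate p < 0.1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "StatResult",
    "normality_gate",
    "compare_groups",
    "adjust_age_sex",
    "correlate",
    "bh_fdr",
    "cognition_regression",
]

SHAPIRO_ALPHA_DEFAULT = 0.05


@dataclass
class StatResult:
    """One comparison or correlation, with room for a stratified adjusted p."""
    comparison: str
    test: str
    statistic: float
    p_raw: float
    effect_size: float                  # Cohen's d, rank-biserial r, or r
    p_adj: Optional[float] = None
    estimate: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n: tuple[int, ...] = ()
    group: str = ""
    family: str = ""


def normality_gate(x: Sequence[float], alpha: float = SHAPIRO_ALPHA_DEFAULT) -> str:
    """'normal' or 'non_normal' by the Shapiro-Wilk test at level alpha."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValidationError(f"normality_gate needs n >= 3, got n={len(x)}")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: treating as non-normal", stacklevel=2)
        return "non_normal"
    _, p = sps.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def compare_groups(values: Sequence[float], groups: Sequence,
                   comparison: str = "", family: str = "",
                   shapiro_alpha: float = SHAPIRO_ALPHA_DEFAULT) -> StatResult:
    """Two-group comparison with a normality-gated choice of test.

    Student's t-test (equal variances, two-sided) with Cohen's d when both
    groups pass Shapiro-Wilk; Mann-Whitney U with the rank-biserial
    correlation otherwise. Group labels follow their order of first
    appearance; the effect sign is first-listed minus second-listed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs n >= 3")
    if a.var() == 0 and b.var() == 0:
        raise ValidationError("both groups constant; comparison degenerate")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        branch = ("normal"
                  if normality_gate(a, shapiro_alpha) == "normal"
                  and normality_gate(b, shapiro_alpha) == "normal"
                  else "non_normal")
    if branch == "normal":
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return StatResult(comparison=comparison, test="student_t",
                          statistic=float(t), p_raw=float(p),
                          effect_size=_cohens_d(a, b),
                          estimate=float(a.mean() - b.mean()),
                          n=(len(a), len(b)), family=family)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    rank_biserial = float(2.0 * u / (len(a) * len(b)) - 1.0)
    return StatResult(comparison=comparison, test="mann_whitney_u",
                      statistic=float(u), p_raw=float(p),
                      effect_size=rank_biserial,
                      estimate=float(np.median(a) - np.median(b)),
                      n=(len(a), len(b)), family=family)


def adjust_age_sex(values: Sequence[float], age: Sequence[float],
                   sex: Sequence, log_transform: bool = False) -> np.ndarray:
    """Age- and sex-adjusted values: OLS residuals plus the grand mean.

    Residualising (rather than keeping covariates in later models) preserves
    the feature's units and scale for plotting and correlation. With
    ``log_transform`` the feature is log-transformed first (the convention for
    non-normally distributed variables) and returned on the log scale.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(age)):
        raise ValidationError("age must be complete (no missing values)")
    sex_codes = pd.Categorical(np.asarray(sex)).codes.astype(float)
    if np.any(sex_codes < 0):
        raise ValidationError("sex must be complete (no missing values)")
    if log_transform:
        if np.any(y[np.isfinite(y)] <= 0):
            raise ValidationError("log transform requires positive values")
        y = np.log(y)

    cols = [np.ones_like(age), age]
    if np.ptp(sex_codes) == 0:
        warnings.warn("single-sex cohort: dropping sex from the adjustment",
                      stacklevel=2)
    else:
        cols.append(sex_codes)
    X = np.column_stack(cols)
    keep = np.isfinite(y)
    beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    out = np.full_like(y, np.nan)
    out[keep] = y[keep] - X[keep] @ beta + y[keep].mean()
    return out


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson",
              comparison: str = "", family: str = "") -> StatResult:
    """Pearson or Spearman correlation over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValidationError(f"correlate needs n >= 4 paired values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero-variance input to correlate")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return StatResult(comparison=comparison, test=method, statistic=float(r),
                      p_raw=float(p), effect_size=float(r), estimate=float(r),
                      n=(len(x),), family=family)


def bh_fdr(results: pd.DataFrame, by: Sequence[str] = ("group", "family"),
           p_col: str = "p_raw", out_col: str = "p_adj") -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment within strata.

    Strata are the unique combinations of the ``by`` columns (by convention
    group membership x parameter-map family), and the adjustment is applied
    independently inside each stratum.
    """
    df = results.copy()
    p = df[p_col].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError(f"{p_col} values must lie in [0, 1]")
    by = [c for c in by if c in df.columns]
    df[out_col] = np.nan
    if by:
        for _, idx in df.groupby(by, dropna=False).groups.items():
            df.loc[idx, out_col] = multipletests(
                df.loc[idx, p_col].to_numpy(), method="fdr_bh")[1]
    else:
        df[out_col] = multipletests(p, method="fdr_bh")[1]
    return df


@dataclass
class RegressionTerm:
    name: str
    b: float
    beta: float
    ci_low: float
    ci_high: float
    p: float
    partial_r: float


@dataclass
class RegressionReport:
    outcome: str
    n: int
    r_squared: float
    terms: list[RegressionTerm] = field(default_factory=list)
    gate_p: Optional[float] = None

    def term(self, name: str) -> RegressionTerm:
        return next(t for t in self.terms if t.name == name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms]).assign(
            outcome=self.outcome, n=self.n)


def cognition_regression(cohort: pd.DataFrame, outcome: str,
                         predictors: Sequence[str],
                         covariates: Sequence[str] = ("age", "male",
                                                      "hydroxycarbamide",
                                                      "transfusion", "sci_burden",
                                                      "etiv", "education_decile"),
                         log_predictors: Sequence[str] = (),
                         gate_alpha: float = 0.1,
                         enforce_gate: bool = True) -> RegressionReport:
    """Multivariable OLS of a cognitive outcome on hemodynamic predictors.

    Complete cases only. Each primary predictor must pass the univariate gate
    (unadjusted correlation with the outcome, p < ``gate_alpha``) unless
    ``enforce_gate`` is False. Predictors listed in ``log_predictors`` enter
    through their natural logarithm. For each term the report carries the
    unstandardised coefficient b, standardised beta = b*sd(x)/sd(y), 95% CI, p
    and the partial correlation r = t / sqrt(t^2 + df_resid).
    """
    cols = [outcome, *predictors, *covariates]
    data = cohort[cols].apply(pd.to_numeric, errors="coerce").dropna()
    design = data.copy()
    rename = {}
    for pred in predictors:
        if pred in log_predictors:
            if np.any(design[pred] <= 0):
                raise ValidationError(f"log transform of {pred} requires positive values")
            design[pred] = np.log(design[pred])
            rename[pred] = f"log_{pred}"
    design = design.rename(columns=rename)
    terms = [rename.get(p_, p_) for p_ in predictors] + list(covariates)

    n = len(design)
    if n <= len(terms) + 2:
        raise ValidationError(
            f"n={n} too small for {len(terms)} model terms")

    gate_p = None
    for pred in predictors:
        r = correlate(design[rename.get(pred, pred)], design[outcome])
        gate_p = r.p_raw if gate_p is None else max(gate_p, r.p_raw)
        if enforce_gate and r.p_raw >= gate_alpha:
            raise ValidationError(
                f"predictor {pred} fails the univariate gate "
                f"(p={r.p_raw:.3f} >= {gate_alpha})")

    X = sm.add_constant(design[terms])
    model = sm.OLS(design[outcome], X).fit()
    ci = model.conf_int(alpha=0.05)
    sd_y = design[outcome].std(ddof=1)
    df_resid = model.df_resid
    report = RegressionReport(outcome=outcome, n=n,
                              r_squared=float(model.rsquared), gate_p=gate_p)
    for name in terms:
        b = float(model.params[name])
        t = float(model.tvalues[name])
        sd_x = design[name].std(ddof=1)
        report.terms.append(RegressionTerm(
            name=name, b=b,
            beta=float(b * sd_x / sd_y) if sd_y > 0 else np.nan,
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1]),
            p=float(model.pvalues[name]),
            partial_r=float(t / np.sqrt(t * t + df_resid))))
    return report
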