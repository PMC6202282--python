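"""Statistical readouts: five-feature avoidance regression, partial
correlation, one-way repeated-measures ANOVA with Sidak post hocs, and
paired one-tailed t-tests.

The avoidance regression models per-subject time in the open region as an
ordinary least-squares function of five behavioral features (speed while
moving, mean movement duration, number of movements, total distance, and
number of movements into the open region).  Predictors are z-scored before
fitting so coefficient magnitudes are comparable; R^2, F and p are
unaffected by the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import CollinearityError, DegenerateDataError, ValidationError

FEATURES = (
    "speed_while_moving",
    "mean_bout_duration",
    "n_movements",
    "total_distance",
    "n_movements_into_open",
)


@dataclass
class RegressionResult:
    """OLS fit summary for the avoidance regression."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    rsquared: float
    nobs: int
    fitted: np.ndarray = field(repr=False, default=None)

    def summary_text(self) -> str:
        lines = [
            f"OLS avoidance regression: n={self.nobs}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f}, "
            f"p = {self.f_pvalue:.2g}, R^2 = {self.rsquared:.3f}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:>24s}: beta = {self.params[name]:+.4f} "
                f"(SE {self.bse[name]:.4f}), t = {self.tvalues[name]:+.2f}, "
                f"p = {self.pvalues[name]:.3g}"
            )
        return "\n".join(lines)


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA over within-subject periods."""

    fvalue: float
    df1: float
    df2: float
    pvalue: float
    epsilon: float               # sphericity correction factor applied (1 = none)
    pairwise: pd.DataFrame       # columns: a, b, t, df, p_uncorrected, p_sidak
    n_subjects: int
    n_excluded: int = 0


def sidak_adjust(p, m: int):
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m (>= p always)."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def avoidance_regression(features: pd.DataFrame,
                         response: str = "time_in_open_pct",
                         predictors: Sequence[str] = FEATURES,
                         standardize: bool = True) -> RegressionResult:
    """OLS of time-in-open on the five behavioral features, with intercept.

    Raises ``CollinearityError`` naming the offending predictors when the
    design matrix is rank deficient (including any constant predictor).
    """
    predictors = list(predictors)
    df = features[predictors + [response]].astype(float)
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValidationError(
            f"need more than {len(predictors) + 1} subjects, got {n}")
    X = df[predictors].to_numpy()
    sd = X.std(axis=0, ddof=1)
    constant = [p for p, s in zip(predictors, sd) if s == 0]
    if constant:
        raise CollinearityError(
            f"constant predictor(s): {', '.join(constant)}", constant)
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    design = sm.add_constant(pd.DataFrame(X, columns=predictors), prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name predictors loading on the null space of the design
        _, sv, vt = np.linalg.svd(design.to_numpy(), full_matrices=False)
        null = np.abs(vt[-1])
        involved = [p for p, w in zip(design.columns, null) if w > 1e-8
                    and p != "const"]
        raise CollinearityError(
            f"rank-deficient design; collinear predictors: "
            f"{', '.join(involved)}", involved)
    fit = sm.OLS(df[response].to_numpy(), design).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
        pvalues=fit.pvalues, fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue), df_model=int(fit.df_model),
        df_resid=int(fit.df_resid), rsquared=float(fit.rsquared), nobs=n,
        fitted=np.asarray(fit.fittedvalues),
    )


def partial_correlation(x, y, control):
    """Correlation of x and y after removing the control variable.

    Both x and y are residualized on [1, control] by least squares; the
    Pearson correlation of the residuals is returned with its p-value on
    n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(x)
    if not (len(y) == len(c) == n):
        raise ValidationError("x, y and control must have equal length")
    if n <= 3:
        raise ValidationError("need n > 3 observations")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    scale = max(np.std(x), np.std(y), 1.0)
    if np.std(rx) < 1e-12 * scale or np.std(ry) < 1e-12 * scale:
        raise DegenerateDataError(
            "zero residual variance after removing the control variable")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 3
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(dof / (1.0 - r_ * r_))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return r, float(p)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (row_means ** 2).sum()
                     + k * k * mean_all ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


def rm_anova_periods(data, correction: Optional[str] = None) -> AnovaResult:
    """One-way repeated-measures ANOVA across matched within-subject levels.

    ``data`` is a subjects x levels DataFrame (e.g. the output of
    :func:`openarms.photometry.period_table`) or an equivalent 2-D array.
    Subjects with any missing level are excluded listwise.  Pairwise level
    contrasts use paired two-sided t-tests with Sidak adjustment.  No
    sphericity correction is applied by default; ``correction='gg'``
    applies Greenhouse-Geisser.
    """
    if isinstance(data, pd.DataFrame):
        levels = [str(c) for c in data.columns]
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        levels = [f"level_{i}" for i in range(arr.shape[1])]
    complete = np.all(np.isfinite(arr), axis=1)
    n_excluded = int((~complete).sum())
    arr = arr[complete]
    n, k = arr.shape
    if n < 3 or k < 2:
        raise ValidationError("need >= 3 complete subjects and >= 2 levels")

    grand = arr.mean()
    ss_subj = k * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_level = n * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_level
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    if ms_err <= 1e-300:
        f = 0.0 if ss_level <= 1e-300 else np.inf
        p = 1.0 if ss_level <= 1e-300 else 0.0
        eps = 1.0
    else:
        f = (ss_level / df1) / ms_err
        eps = _gg_epsilon(arr) if correction == "gg" else 1.0
        p = float(sps.f.sf(f, df1 * eps, df2 * eps))

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        d = arr[:, i] - arr[:, j]
        sd = d.std(ddof=1)
        if sd == 0:
            t, p_unc = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
        else:
            t = float(d.mean() / (sd / np.sqrt(n)))
            p_unc = float(2.0 * sps.t.sf(abs(t), n - 1))
        rows.append({"a": levels[i], "b": levels[j], "t": t, "df": n - 1,
                     "p_uncorrected": p_unc,
                     "p_sidak": float(sidak_adjust(p_unc, len(pairs)))})
    return AnovaResult(fvalue=float(f), df1=df1 * eps, df2=df2 * eps,
                       pvalue=float(p), epsilon=eps,
                       pairwise=pd.DataFrame(rows), n_subjects=n,
                       n_excluded=n_excluded)


def paired_onetailed(a, b, direction: str = "greater"):
    """Paired t-test on a - b with a one-sided p in the stated direction.

    ``direction='greater'`` tests a > b.  Equal inputs give p = 0.5;
    zero-variance non-zero differences raise ``DegenerateDataError``.
    """
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("a and b must have equal length")
    if len(a) < 2:
        raise ValidationError("need n >= 2 pairs")
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 0.5
    if d.std(ddof=1) == 0:
        raise DegenerateDataError("paired differences have zero variance")
    res = sps.ttest_rel(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue)
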