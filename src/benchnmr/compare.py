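"""Four-method agreement statistics: two-way variance-components ANOVA,
Tukey HSD on method means, and pairwise agreement regressions.

The measurement model is y_ij = µ + M_i + P_j + e_ij with method a fixed
effect and participant a random effect; in the balanced one-observation-per-
cell design the participant variance component follows from the expected
mean squares, σ²_P = (MS_P − MS_E)/a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AnovaResult",
    "variance_components_anova",
    "tukey_hsd",
    "AgreementFit",
    "agreement_regression",
]


@dataclass
class AnovaResult:
    ss_method: float
    ss_participant: float
    ss_error: float
    df_method: int
    df_participant: int
    df_error: int
    F_method: float
    F_participant: float
    p_method: float
    p_participant: float
    var_participant: float
    var_error: float
    var_participant_truncated: bool
    table: pd.DataFrame  # participants × methods cell means


def _pivot_balanced(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "method", "concentration"}
    if not required <= set(table.columns):
        raise ValueError(f"long-format table needs columns {sorted(required)}")
    cell = table.pivot_table(index="participant", columns="method",
                             values="concentration", aggfunc="mean")
    if cell.isna().any().any():
        raise ValueError(
            "unbalanced design (missing participant × method cells); use a "
            "mixed-model/regression analysis instead")
    if cell.shape[0] < 2 or cell.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 methods")
    return cell


def variance_components_anova(table: pd.DataFrame) -> AnovaResult:
    """Two-way ANOVA (method fixed, participant random), balanced design.

    Replicated cells are averaged before the closed-form sums-of-squares
    partition; SS_total = SS_method + SS_participant + SS_error exactly.
    A negative participant variance estimate truncates to 0 with a flag.
    """
    cell = _pivot_balanced(table)
    Y = cell.to_numpy(dtype=float)
    n_p, n_m = Y.shape
    grand = Y.mean()
    ss_m = n_p * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_p = n_m * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_e = ((Y - Y.mean(axis=0)[None, :] - Y.mean(axis=1)[:, None]
             + grand) ** 2).sum()
    df_m, df_p = n_m - 1, n_p - 1
    df_e = df_m * df_p
    ms_m, ms_p, ms_e = ss_m / df_m, ss_p / df_p, ss_e / df_e
    if ms_e == 0:
        F_m = F_p = 0.0
        p_m = p_p = 1.0
        if ms_m > 0:
            F_m, p_m = np.inf, 0.0
        if ms_p > 0:
            F_p, p_p = np.inf, 0.0
    else:
        F_m, F_p = ms_m / ms_e, ms_p / ms_e
        p_m = float(stats.f.sf(F_m, df_m, df_e))
        p_p = float(stats.f.sf(F_p, df_p, df_e))
    var_p = (ms_p - ms_e) / n_m
    truncated = var_p < 0
    return AnovaResult(
        ss_method=float(ss_m), ss_participant=float(ss_p),
        ss_error=float(ss_e), df_method=df_m, df_participant=df_p,
        df_error=df_e, F_method=float(F_m), F_participant=float(F_p),
        p_method=p_m, p_participant=p_p,
        var_participant=float(max(var_p, 0.0)), var_error=float(ms_e),
        var_participant_truncated=bool(truncated), table=cell)


def tukey_hsd(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Studentised-range comparisons of method means.

    Uses the two-way residual mean square as the error term (the correct
    denominator in the blocked-by-participant design).  Returns one row per
    method pair with the difference, q statistic, adjusted p, CI and flag.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    res = variance_components_anova(table)
    cell = res.table
    n_p, n_m = cell.shape
    means = cell.mean(axis=0)
    se = np.sqrt(res.var_error / n_p)
    q_crit = stats.studentized_range.ppf(1 - alpha, n_m, res.df_error)
    rows = []
    methods = list(cell.columns)
    for i in range(n_m):
        for j in range(i + 1, n_m):
            diff = means.iloc[i] - means.iloc[j]
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, n_m, res.df_error))
            half = q_crit * se
            rows.append({
                "method_a": methods[i], "method_b": methods[j],
                "difference": float(diff), "q": float(q), "p_adj": p,
                "ci_low": float(diff - half), "ci_high": float(diff + half),
                "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


@dataclass
class AgreementFit:
    slope: float
    intercept: float
    r2: float
    slope_ci: tuple
    intercept_ci: tuple
    slope_covers_1: bool
    intercept_covers_0: bool
    n: int


def agreement_regression(x, y, alpha: float = 0.05) -> AgreementFit:
    """OLS agreement fit of y on x with t-based CIs and coverage flags.

    Flags report whether the slope CI covers 1.00 and the intercept CI
    covers 0.00 — the two conditions for between-method agreement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("x values are constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    icpt_ci = (float(ci[0][0]), float(ci[0][1]))
    slope_ci = (float(ci[1][0]), float(ci[1][1]))
    return AgreementFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), slope_ci=slope_ci, intercept_ci=icpt_ci,
        slope_covers_1=bool(slope_ci[0] <= 1.0 <= slope_ci[1]),
        intercept_covers_0=bool(icpt_ci[0] <= 0.0 <= icpt_ci[1]),
        n=int(x.size))
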