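"""Behavioural outcome measures and group statistics.

Performance error (mean absolute distance between predictions and the
distribution EV — the EV being the optimal prediction), classification of
agents into "scalers" vs "non-scalers" by the fitted PE-scaling extent nu,
the associated 2x2 contingency and Pearson chi-square, covariate
residualisation, parametric/nonparametric group comparisons with post hoc
tests restricted to control-vs-treatment, and a regression of overall
performance error on the fitted learning parameters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "performance_error",
    "model_r2",
    "scaling_contingency",
    "pearson_chi2",
    "residualize",
    "group_tests",
    "performance_regression",
    "SCALER_EPSILON",
]

#: nu at or below this is a boundary estimate, i.e. "no PE scaling".
SCALER_EPSILON = 1e-3


def performance_error(
    trials: pd.DataFrame, by_sd: bool = True
) -> pd.Series | float:
    """Mean |prediction - EV| over non-missed trials.

    With ``by_sd`` true, returns one value per SD condition plus an
    ``overall`` entry (the mean over all trials); conditions with no valid
    trials are missing.
    """
    ok = trials[~trials["missed"].astype(bool)].copy()
    ok = ok[~ok["prediction"].isna()]
    if ok.empty:
        raise ValueError("no non-missed trials with predictions")
    err = (ok["prediction"] - ok["ev"]).abs()
    if not by_sd:
        return float(err.mean())
    per_sd = err.groupby(ok["sd"]).mean()
    out = {f"sd{sd:g}": float(v) for sd, v in per_sd.items()}
    out["overall"] = float(err.mean())
    return pd.Series(out)


def model_r2(trials: pd.DataFrame, mu: np.ndarray) -> float:
    """Squared correlation between observed predictions and model means.

    Computed per SD condition and averaged over conditions, summarising how
    closely model-generated predictions track the observed sequence.
    """
    ok = trials.sort_values(["session", "trial"], kind="stable")
    ok = ok[~ok["missed"].astype(bool)]
    y = ok["prediction"].to_numpy(dtype=float)
    if y.size != np.size(mu):
        raise ValueError("mu must align with the non-missed trials")
    sds = ok["sd"].to_numpy(dtype=float)
    r2s = []
    for sd in np.unique(sds):
        m = sds == sd
        if m.sum() < 3 or np.std(y[m]) == 0 or np.std(np.asarray(mu)[m]) == 0:
            continue
        r = np.corrcoef(y[m], np.asarray(mu)[m])[0, 1]
        r2s.append(r * r)
    if not r2s:
        raise ValueError("no condition with enough variance to correlate")
    return float(np.mean(r2s))


def scaling_contingency(
    nu: pd.Series,
    groups: pd.Series,
    group_order: tuple[str, str],
    epsilon: float = SCALER_EPSILON,
) -> np.ndarray:
    """2x2 counts of non-scalers (nu <= epsilon) vs scalers by group.

    Rows follow ``group_order``; columns are (non-scaler, scaler).
    """
    counts = np.zeros((2, 2), dtype=int)
    for i, g in enumerate(group_order):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"unknown or empty group {g!r}")
        vals = nu[mask]
        counts[i, 0] = int((vals <= epsilon).sum())
        counts[i, 1] = int((vals > epsilon).sum())
    return counts


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence, without continuity correction.

    Returns (statistic, df, p).  The Yates correction is deliberately
    omitted; this is the plain sum of (O - E)^2 / E.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def residualize(outcome, covariate) -> np.ndarray:
    """Z-scored OLS residuals of outcome on covariate (with intercept).

    Used to remove nuisance variance (e.g. the time from dosing to scan)
    before group comparisons.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size:
        raise ValueError("outcome and covariate must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations to residualize")
    if np.std(x) == 0:
        raise ValueError("covariate is constant")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    s = resid.std(ddof=0)
    if s < 1e-12:
        raise ValueError("residuals are degenerate (outcome fully explained)")
    return (resid - resid.mean()) / s


def group_tests(
    values,
    groups,
    control: str = "placebo",
    parametric: bool = True,
    posthoc_alpha: float = 0.025,
) -> dict:
    """Omnibus group comparison plus control-vs-treatment post hoc tests.

    Parametric route: one-way ANOVA omnibus and Welch-free two-sample t post
    hocs.  Nonparametric route: Kruskal-Wallis omnibus and Wilcoxon rank-sum
    post hocs (for metrics that are not normally distributed).  Post hocs
    are restricted to the control group versus each treatment group, at a
    Bonferroni-style alpha (0.025 for two comparisons).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in labels}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if control not in samples:
        raise ValueError(f"control group {control!r} not present")

    if parametric:
        stat, p = stats.f_oneway(*samples.values())
        omnibus = {"test": "one-way ANOVA", "statistic": float(stat),
                   "p": float(p)}
    else:
        stat, p = stats.kruskal(*samples.values())
        omnibus = {"test": "Kruskal-Wallis", "statistic": float(stat),
                   "p": float(p)}

    posthoc = []
    for g in labels:
        if g == control:
            continue
        if parametric:
            t, pp = stats.ttest_ind(samples[control], samples[g])
            posthoc.append({"comparison": f"{control} vs {g}",
                            "test": "t", "statistic": float(t),
                            "p": float(pp),
                            "significant": bool(pp < posthoc_alpha)})
        else:
            z, pp = stats.ranksums(samples[control], samples[g])
            posthoc.append({"comparison": f"{control} vs {g}",
                            "test": "rank-sum", "statistic": float(z),
                            "p": float(pp),
                            "significant": bool(pp < posthoc_alpha)})
    return {"omnibus": omnibus, "posthoc": posthoc,
            "posthoc_alpha": posthoc_alpha,
            "underpowered": bool(min(v.size for v in samples.values()) < 5)}


def performance_regression(cohort: pd.DataFrame) -> pd.DataFrame:
    """Regress overall performance error on the fitted learning parameters.

    Predictors: scaler status (nu above the boundary, entered as a 0/1
    indicator), initial learning rate k1 and decay gamma, with treatment
    group as a categorical covariate.  Returns per-predictor coefficient,
    t and p.
    """
    required = {"perf_error", "nu", "k1", "gamma", "group"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort frame missing columns: {sorted(missing)}")
    df = cohort.copy()
    df["scaler"] = (df["nu"] > SCALER_EPSILON).astype(float)
    X = pd.concat(
        [df[["scaler", "k1", "gamma"]],
         pd.get_dummies(df["group"], prefix="group", drop_first=True,
                        dtype=float)],
        axis=1,
    )
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(df["perf_error"].to_numpy(dtype=float), X).fit()
    return pd.DataFrame({
        "coef": fit.params, "t": fit.tvalues, "p": fit.pvalues,
    })
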