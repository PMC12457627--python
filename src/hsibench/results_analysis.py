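"""Factor analysis over combination results: ANOVA, OLS contrasts, diagnostics.

The benchmark's output is a results table with one row per preprocessing
combination — factor levels (scaling, smoothing mode/filter/param, blood
threshold, light threshold, weighting, patch size) plus the MSS response.
"none" is a level, not a missing value, so the no-smoothing / no-filtering
baselines enter the models like any other level.

Three analysis stages mirror the study's workflow:

* :func:`anova_factors` — a main-effects linear model with Type II ANOVA
  giving each factor's F statistic and p-value, plus overall R² and the
  model F-test p;
* :func:`ols_contrasts` — dummy-coded OLS of one contributor family against
  its "none" baseline, reporting per-level coefficient, two-tailed p and 95%
  confidence interval (run separately per family: smoothing, blood, light);
* :func:`vif_check` / :func:`residual_qq` — variance-inflation factors per
  predictor and a Shapiro–Wilk residual-normality summary.

No multiple-testing correction is applied by default (raw p-values are
reported); Holm adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import dmatrix
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

DEFAULT_FACTORS = (
    "scaling",
    "smoothing_mode",
    "smoothing_filter",
    "smoothing_param",
    "blood_threshold",
    "light_threshold",
    "weighting",
    "patch_size",
)


@dataclass
class FactorReport:
    anova: pd.DataFrame | None = None
    model_r2: float | None = None
    model_f_p: float | None = None
    ols: pd.DataFrame | None = None
    vif: pd.Series | None = None
    residual_normality: dict = field(default_factory=dict)


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a results table; validates the response range."""
    table = pd.DataFrame(rows)
    if "mss" not in table.columns:
        raise ValueError("results table requires an 'mss' column")
    if ((table["mss"] < 0) | (table["mss"] > 1)).any():
        raise ValueError("mss values must lie in [0, 1]")
    return table


def _usable_factors(table: pd.DataFrame, factors) -> list[str]:
    out = []
    for f in factors:
        n_levels = table[f].astype(str).nunique()
        if n_levels < 2:
            raise ValueError(f"factor {f!r} has a single level; drop it from the model")
        out.append(f)
    return out


def _formula(factors) -> str:
    return "mss ~ " + " + ".join(f"C({f})" for f in factors)


def anova_factors(table: pd.DataFrame, factors=None) -> FactorReport:
    """Type II ANOVA over a main-effects model of the listed factors."""
    factors = _usable_factors(table, factors if factors is not None else
                              [f for f in DEFAULT_FACTORS if f in table.columns
                               and table[f].astype(str).nunique() > 1])
    y = table["mss"].to_numpy(float)
    report = FactorReport()
    if np.ptp(y) < 1e-12:
        # constant response: zero explainable and residual variance by
        # convention F = 0, p = 1 for every factor
        report.anova = pd.DataFrame(
            {"F": [0.0] * len(factors), "PR(>F)": [1.0] * len(factors)},
            index=factors,
        )
        report.model_r2 = 0.0
        report.model_f_p = 1.0
        return report
    fit = smf.ols(_formula(factors), data=table).fit()
    aov = anova_lm(fit, typ=2)
    aov = aov.loc[[f"C({f})" for f in factors], ["F", "PR(>F)"]]
    aov.index = factors
    report.anova = aov
    report.model_r2 = float(fit.rsquared)
    report.model_f_p = float(fit.f_pvalue)
    return report


def ols_contrasts(
    table: pd.DataFrame,
    factor: str,
    baseline: str = "none",
    holm: bool = False,
) -> pd.DataFrame:
    """Dummy-coded OLS of one factor against its baseline level.

    Each row is one non-baseline level: the coefficient is its estimated MSS
    change versus the baseline, with two-tailed p-value and 95% CI. ``holm``
    applies a Holm step-down adjustment to the p-values.
    """
    levels = table[factor].astype(str)
    if baseline not in set(levels):
        raise ValueError(f"baseline level {baseline!r} absent from factor {factor!r}")
    fit = smf.ols(
        f"mss ~ C({factor}, Treatment(reference={baseline!r}))", data=table
    ).fit()
    conf = fit.conf_int(alpha=0.05)
    rows = []
    prefix = f"C({factor}, Treatment(reference={baseline!r}))[T."
    for name in fit.params.index:
        if not name.startswith(prefix):
            continue
        level = name[len(prefix) : -1]
        rows.append(
            {
                "level": level,
                "coefficient": float(fit.params[name]),
                "p_value": float(fit.pvalues[name]),
                "ci_low": float(conf.loc[name, 0]),
                "ci_high": float(conf.loc[name, 1]),
            }
        )
    out = pd.DataFrame(rows).set_index("level")
    if holm and len(out):
        out["p_value"] = multipletests(out["p_value"].to_numpy(), method="holm")[1]
    return out


def vif_check(table: pd.DataFrame, factors=None) -> pd.Series:
    """VIF per dummy predictor of the main-effects design (1/(1-R²_j)).

    Infinite VIFs (aliased/duplicated predictors) are returned as ``inf`` so
    callers can flag them.
    """
    factors = _usable_factors(table, factors if factors is not None else
                              [f for f in DEFAULT_FACTORS if f in table.columns
                               and table[f].astype(str).nunique() > 1])
    design = dmatrix(" + ".join(f"C({f})" for f in factors), data=table,
                     return_type="dataframe")
    cols = [c for c in design.columns if c != "Intercept"]
    X = design.to_numpy(float)
    idx = [design.columns.get_loc(c) for c in cols]
    with np.errstate(divide="ignore"):
        values = [variance_inflation_factor(X, i) for i in idx]
    return pd.Series(values, index=cols, name="vif")


def residual_qq(table: pd.DataFrame, factors=None) -> dict:
    """Shapiro–Wilk residual-normality summary of the main-effects fit.

    Returns ``{"statistic", "p_value", "normal_at_05"}``; a p-value above
    0.05 means normality is not rejected (the Q-Q check the OLS stage
    assumes).
    """
    factors = _usable_factors(table, factors if factors is not None else
                              [f for f in DEFAULT_FACTORS if f in table.columns
                               and table[f].astype(str).nunique() > 1])
    fit = smf.ols(_formula(factors), data=table).fit()
    resid = np.asarray(fit.resid, dtype=float)
    stat, p = stats.shapiro(resid)
    return {"statistic": float(stat), "p_value": float(p), "normal_at_05": bool(p > 0.05)}


def summarize_groups(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Exact order statistics of MSS per level of ``by``.

    Mirrors the boxplot summaries: per level median, max, quartiles and n;
    when a "none" level exists its median/max are echoed in columns
    ``baseline_median`` / ``baseline_max`` for comparison.
    """
    grouped = table.groupby(table[by].astype(str))["mss"]
    out = grouped.agg(
        median="median",
        max="max",
        q1=lambda s: float(np.percentile(s, 25)),
        q3=lambda s: float(np.percentile(s, 75)),
        n="count",
    )
    if "none" in out.index:
        out["baseline_median"] = out.loc["none", "median"]
        out["baseline_max"] = out.loc["none", "max"]
    return out
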