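"""Univariate change-score regressions and concurrent-validity models.

Measures are pooled z-scored (mean/SD over all participants and both
sessions), differenced (post - pre), and each difference is regressed on an
intercept plus the intervention dummy (positive arm = 1): the intercept
estimates the negative-arm mean change and the intervention coefficient the
between-arm change difference. Familywise error within each variable group
is controlled by Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("affectpipe.stats")

__all__ = [
    "RegressionResult",
    "compute_change_table",
    "change_from_sessions",
    "fit_change_regression",
    "run_change_regressions",
    "bonferroni_alpha",
    "concurrent_validity",
]


@dataclass
class RegressionResult:
    measure: str
    intercept: float
    intercept_p: float
    intervention_coef: float
    intervention_p: float
    n: int
    family: str = ""
    alpha_adjusted: float = 0.05


def compute_change_table(cohort) -> pd.DataFrame:
    """Per-participant standardized change scores z(post) - z(pre).

    z-scoring uses the mean and SD pooled over all participants and both
    sessions of each measure; zero-variance measures are dropped with a
    warning. Returns a frame with a ``condition`` column plus one change
    column per retained measure.
    """
    out = pd.DataFrame({"condition": cohort.condition})
    for m in cohort.measures:
        pooled = np.concatenate([cohort.pre[m].to_numpy(), cohort.post[m].to_numpy()])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("measure %r has zero pooled SD; dropped", m)
            continue
        out[m] = (cohort.post[m] - mu) / sd - (cohort.pre[m] - mu) / sd
    return out


def change_from_sessions(table: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Pooled-z change scores from a (participant, session)-indexed table.

    ``table`` is indexed by (participant_id, session) with session values
    "pre"/"post", one column per measure -- the layout emitted by the
    cognitive scorer and the physiological feature extractors. Same pooled
    z-scoring rule as :func:`compute_change_table`.
    """
    pre = table.xs("pre", level="session")
    post = table.xs("post", level="session")
    common = pre.index.intersection(post.index).intersection(condition.index)
    out = pd.DataFrame({"condition": condition.loc[common]})
    for m in table.columns:
        pooled = np.concatenate([pre.loc[common, m], post.loc[common, m]])
        pooled = pooled[np.isfinite(pooled)]
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("measure %r has zero pooled SD; dropped", m)
            continue
        out[m] = (post.loc[common, m] - mu) / sd - (pre.loc[common, m] - mu) / sd
    return out


def fit_change_regression(
    changes: np.ndarray | pd.Series,
    condition: np.ndarray | pd.Series,
    *,
    measure: str = "",
    family: str = "",
    alpha_adjusted: float = 0.05,
) -> RegressionResult:
    """OLS of change on {1, condition}; two-sided t-test p-values.

    The intercept equals the negative-arm mean change and intercept +
    coefficient the positive-arm mean change.
    """
    y = np.asarray(changes, dtype=float)
    cond = np.asarray(condition, dtype=float)
    if len(np.unique(cond)) < 2:
        raise ValueError("both intervention conditions must be represented")
    X = sm.add_constant(cond)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        measure=measure,
        intercept=float(fit.params[0]),
        intercept_p=float(fit.pvalues[0]),
        intervention_coef=float(fit.params[1]),
        intervention_p=float(fit.pvalues[1]),
        n=len(y),
        family=family,
        alpha_adjusted=alpha_adjusted,
    )


def run_change_regressions(
    change_table: pd.DataFrame, family: str, familywise: float = 0.05
) -> pd.DataFrame:
    """One change regression per measure column; tidy results frame.

    The Bonferroni-adjusted alpha uses the family size = number of measures
    in the table.
    """
    measures = [c for c in change_table.columns if c != "condition"]
    alpha = bonferroni_alpha(len(measures), familywise)
    rows = []
    for m in measures:
        res = fit_change_regression(
            change_table[m], change_table["condition"],
            measure=m, family=family, alpha_adjusted=alpha,
        )
        rows.append(
            {
                "measure": m,
                "family": family,
                "intercept": res.intercept,
                "intercept_p": res.intercept_p,
                "intervention_coef": res.intervention_coef,
                "intervention_p": res.intervention_p,
                "n": res.n,
                "alpha_adjusted": alpha,
                "significant": res.intervention_p < alpha,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_alpha(family_size: int, familywise: float = 0.05) -> float:
    """Familywise alpha divided by the family size (18 cognitive measures
    give 0.0028; 14 self-report measures give 0.0036)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return familywise / family_size


def _name_collinear(X: pd.DataFrame) -> list[str]:
    """Columns that are (near-)linear combinations of the preceding ones."""
    bad = []
    arr = np.column_stack([np.ones(len(X))])
    for col in X.columns:
        cand = np.column_stack([arr, X[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand, tol=1e-8) == arr.shape[1]:
            bad.append(col)
        else:
            arr = cand
    return bad


def concurrent_validity(
    dv_table: pd.DataFrame,
    feature_table: pd.DataFrame,
    dv_names: list[str] | None = None,
    familywise: float = 0.05,
) -> pd.DataFrame:
    """One OLS per self-report DV with every feature of the set as IVs.

    Returns per DV the overall F statistic and p-value, R^2, the
    coefficient table (as nested records), and a significance flag at the
    Bonferroni-adjusted alpha (familywise / number of DVs).
    """
    if dv_names is None:
        dv_names = list(dv_table.columns)
    common = dv_table.index.intersection(feature_table.index)
    if len(common) == 0:
        raise ValueError("DV and feature tables share no participants")
    dv_table = dv_table.loc[common]
    features = feature_table.loc[common]
    if len(common) <= features.shape[1] + 1:
        raise ValueError(
            f"need n > number of IVs + 1 ({features.shape[1] + 1}), got n={len(common)}"
        )
    X = sm.add_constant(features.to_numpy(dtype=float))
    if np.linalg.matrix_rank(X, tol=1e-8) < X.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + ", ".join(_name_collinear(features))
        )
    alpha = bonferroni_alpha(len(dv_names), familywise)
    rows = []
    for dv in dv_names:
        fit = sm.OLS(dv_table[dv].to_numpy(dtype=float), X).fit()
        coefs = [
            {
                "iv": name,
                "coef": float(fit.params[i]),
                "p": float(fit.pvalues[i]),
            }
            for i, name in enumerate(["Intercept"] + list(features.columns))
        ]
        rows.append(
            {
                "dv": dv,
                "f_stat": float(fit.fvalue),
                "f_p": float(fit.f_pvalue),
                "r_squared": float(fit.rsquared),
                "alpha_adjusted": alpha,
                "significant": float(fit.f_pvalue) < alpha,
                "coefficients": coefs,
            }
        )
    return pd.DataFrame(rows)
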