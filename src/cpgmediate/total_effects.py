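"""Total effects of cumulative stress on cardiometabolic outcomes.

Model 1 regresses each outcome on the cumulative stress score adjusting
for age, sex, education, measurement year and ten ancestry PCs (plus
fasting status for the blood-draw lipid/glucose outcomes); Model 2 adds
smoking-status categories.  The fraction of outcome variance explained by
stress is the change in R-squared between the full Model-1 fit and the
same fit without the stress term, divided by the full-model R-squared.
Outcomes with Model-1 p < 0.05 are gated into mediation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TotalEffectResult",
    "build_covariates",
    "fit_total_effect",
    "variance_explained",
    "compare_cohorts",
    "FASTING_OUTCOMES",
]

#: Outcomes whose models include fasting status as a covariate.
FASTING_OUTCOMES = ("glucose", "HDL-C", "LDL-C", "TG")

CATEGORICAL = ("sex", "education", "smoking", "measurement_year")


class CollinearityError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class ContractError(ValueError):
    """Fits are not nested or not on the same rows."""


@dataclass
class TotalEffectResult:
    outcome: str
    model: int
    coef: float          # outcome units per SD of stress
    se: float
    p_value: float
    r2_full: float
    r2_reduced: float
    variance_explained: float
    n: int


def build_covariates(
    pheno: pd.DataFrame,
    include_smoking: bool = False,
    include_fasting: bool = False,
) -> pd.DataFrame:
    """Numeric covariate frame: age, ancestry PCs, category dummies.

    Unordered categoricals (sex, education, smoking, measurement year)
    enter as dummies with the first level as reference.
    """
    parts = [pheno[["age"]].astype(float)]
    pc_cols = [c for c in pheno.columns if c.startswith("ancestry_pc")]
    parts.append(pheno[pc_cols].astype(float))
    cats = ["sex", "education", "measurement_year"]
    if include_smoking:
        cats.append("smoking")
    for c in cats:
        d = pd.get_dummies(pheno[c].astype("category"), prefix=c,
                           drop_first=True, dtype=float)
        parts.append(d)
    if include_fasting:
        parts.append(pheno[["fasting"]].astype(float))
    return pd.concat(parts, axis=1)


def _check_design(d: np.ndarray) -> None:
    if d.shape[0] <= d.shape[1]:
        raise InsufficientDataError(
            f"n={d.shape[0]} rows for {d.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(d) < d.shape[1]:
        raise CollinearityError("design matrix is rank deficient")


def fit_total_effect(
    y: pd.Series,
    x: pd.Series,
    covariates: pd.DataFrame | None,
    outcome: str = "",
    model: int = 1,
) -> TotalEffectResult:
    """OLS total effect of stress on one outcome, complete cases only.

    ``covariates`` is a numeric frame (see :func:`build_covariates`); pass
    ``None`` for an intercept-only adjustment set.  Returns the stress
    coefficient with its two-sided t-test p-value, the R-squared of the
    fit with and without the stress term, and the variance-explained
    fraction.
    """
    df = pd.DataFrame({"_y": y, "_x": x})
    if covariates is not None:
        df = pd.concat([df, covariates], axis=1)
    df = df.dropna()
    if df.empty:
        raise InsufficientDataError("no complete cases")
    yv = df["_y"].to_numpy(dtype=float)
    xv = df["_x"].to_numpy(dtype=float)
    cv = df.drop(columns=["_y", "_x"]).to_numpy(dtype=float)

    exog_full = sm.add_constant(np.column_stack([xv, cv]) if cv.size else xv[:, None])
    _check_design(exog_full)
    fit_full = sm.OLS(yv, exog_full).fit()
    exog_red = sm.add_constant(cv) if cv.size else np.ones((len(yv), 1))
    fit_red = sm.OLS(yv, exog_red).fit()

    return TotalEffectResult(
        outcome=outcome,
        model=model,
        coef=float(fit_full.params[1]),
        se=float(fit_full.bse[1]),
        p_value=float(fit_full.pvalues[1]),
        r2_full=float(fit_full.rsquared),
        r2_reduced=float(fit_red.rsquared),
        variance_explained=variance_explained(fit_full, fit_red),
        n=int(fit_full.nobs),
    )


def variance_explained(fit_full, fit_reduced) -> float:
    """(R2_full - R2_reduced) / R2_full for nested fits on the same rows."""
    if int(fit_full.nobs) != int(fit_reduced.nobs):
        raise ContractError("fits use different numbers of rows")
    if fit_full.df_model < fit_reduced.df_model:
        raise ContractError("full model has fewer terms than reduced model")
    r2f, r2r = float(fit_full.rsquared), float(fit_reduced.rsquared)
    if r2f + 1e-300 < r2r:
        raise ContractError("R2_full < R2_reduced: models are not nested")
    if r2f <= 0:
        return 0.0
    return max(0.0, (r2f - r2r) / r2f)


def total_effects_table(
    pheno: pd.DataFrame,
    exposure: pd.Series,
    outcomes: dict[str, pd.Series],
    model: int = 1,
) -> pd.DataFrame:
    """Fit the total-effect model for each outcome; one row per outcome."""
    rows = []
    for name, y in outcomes.items():
        cov = build_covariates(
            pheno,
            include_smoking=(model == 2),
            include_fasting=name in FASTING_OUTCOMES,
        )
        res = fit_total_effect(y, exposure, cov, outcome=name, model=model)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Included/excluded cohort comparison
# ---------------------------------------------------------------------------

def _cramers_v(table: np.ndarray) -> tuple[float, float, float]:
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    k = min(table.shape[0] - 1, table.shape[1] - 1)
    v = float(np.sqrt(chi2 / (n * max(k, 1))))
    return float(chi2), float(p), v


def _cohens_d(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    t, p = stats.ttest_ind(a, b, equal_var=True)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    return float(t), float(p), d


def compare_cohorts(
    included: pd.DataFrame,
    excluded: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "education", "smoking"),
    continuous: tuple[str, ...] = ("age",),
) -> pd.DataFrame:
    """Included-vs-excluded comparison: chi-square + Cramer's V for
    categorical variables, two-sample t-test + Cohen's d (pooled SD) for
    continuous ones."""
    if included.empty or excluded.empty:
        raise InsufficientDataError("both groups must be non-empty")
    rows = []
    for var in categorical:
        levels = sorted(set(included[var].dropna()) | set(excluded[var].dropna()))
        tab = np.array(
            [
                included[var].value_counts().reindex(levels, fill_value=0),
                excluded[var].value_counts().reindex(levels, fill_value=0),
            ]
        )
        stat, p, es = _cramers_v(tab)
        rows.append(
            {"variable": var, "type": "categorical", "statistic": stat,
             "p_value": p, "effect_size": es, "effect_size_name": "cramers_v"}
        )
    for var in continuous:
        a = included[var].dropna().to_numpy(dtype=float)
        b = excluded[var].dropna().to_numpy(dtype=float)
        stat, p, es = _cohens_d(a, b)
        rows.append(
            {"variable": var, "type": "continuous", "statistic": stat,
             "p_value": p, "effect_size": es, "effect_size_name": "cohens_d"}
        )
    return pd.DataFrame(rows)
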