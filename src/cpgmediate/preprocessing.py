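"""Methylation and outcome preprocessing.

Methylation pipeline (order fixed): per-CpG mean imputation of missing
beta values -> per-CpG winsorization at the Tukey-style fences
[Q1 - 3*IQR, Q3 + 3*IQR] -> residualization on estimated white-blood-cell
proportions plus plate and position terms, with residuals re-centered at
the CpG mean so values stay on a beta-like scale.

Outcome pipeline: removal (not clamping) of values outside the same
3*IQR fences -> medication adjustment (SBP +15 / DBP +10 mm Hg under
antihypertensives; LDL-C / 0.7 and TC / 0.8 under statins; HDL-C and TG
never adjusted; glucose excluded, not adjusted, under diabetes
medication) -> natural-log transform of glucose and CRP.

Quantiles use linear interpolation (type 7).  Plate and position enter as
fixed-effect dummies; per-CpG OLS residuals are deterministic and, for
balanced designs, match the random-effects adjustment in expectation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_impute",
    "winsorize_3iqr",
    "residualize_methylation",
    "remove_outcome_outliers",
    "adjust_medication",
    "log_transform",
    "preprocess_methylation",
    "preprocess_outcome",
    "OUTCOMES",
    "LOG_OUTCOMES",
]

#: Recognized cardiometabolic outcomes.
OUTCOMES = ("BMI", "WC", "SBP", "DBP", "LDL-C", "TC", "HDL-C", "TG", "glucose", "CRP")
#: Outcomes receiving a natural-log transform.
LOG_OUTCOMES = ("glucose", "CRP")

LABEL_COLS = ("plate", "position_row", "position_col")


class UnprocessableColumnError(ValueError):
    """A CpG column cannot be processed (e.g. all values missing)."""


class DegenerateInputError(ValueError):
    """Vector too short or degenerate for fence computation."""


class CollinearityError(ValueError):
    """Nuisance design is rank deficient."""


class SchemaError(KeyError):
    """Unknown outcome name."""


class DomainError(ValueError):
    """Values outside the mathematical domain of a transform."""


def _split_labels(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = m[[c for c in LABEL_COLS if c in m.columns]]
    values = m.drop(columns=labels.columns)
    return values, labels


def mean_impute(m: pd.DataFrame) -> pd.DataFrame:
    """Replace missing beta values by the CpG's observed mean."""
    values, labels = _split_labels(m)
    all_missing = values.columns[values.isna().all()]
    if len(all_missing):
        raise UnprocessableColumnError(
            f"all-missing CpG columns: {list(all_missing[:5])}"
        )
    filled = values.fillna(values.mean())
    return pd.concat([labels, filled], axis=1)


def _fences(v: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    return q1 - 3.0 * iqr, q3 + 3.0 * iqr


def winsorize_3iqr(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Clamp values outside [Q1 - 3*IQR, Q3 + 3*IQR] to the fences."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise DegenerateInputError("need >= 4 values for fence computation")
    lo, hi = _fences(v)
    out = np.clip(v, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def winsorize_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Column-wise winsorization of a methylation matrix."""
    values, labels = _split_labels(m)
    arr = values.to_numpy(dtype=float)
    q1 = np.quantile(arr, 0.25, axis=0)
    q3 = np.quantile(arr, 0.75, axis=0)
    iqr = q3 - q1
    out = np.clip(arr, q1 - 3 * iqr, q3 + 3 * iqr)
    res = pd.DataFrame(out, index=values.index, columns=values.columns)
    return pd.concat([labels, res], axis=1)


def _nuisance_design(
    cells: pd.DataFrame, plate: pd.Series, pos_row: pd.Series, pos_col: pd.Series
) -> np.ndarray:
    """Intercept + K-1 cell proportions + plate/position dummies."""
    parts = [np.ones((len(cells), 1))]
    # Drop the last cell type: proportions sum to one.
    parts.append(cells.to_numpy(dtype=float)[:, :-1])
    for lab in (plate, pos_row, pos_col):
        d = pd.get_dummies(lab, drop_first=True, dtype=float)
        if d.shape[1]:
            parts.append(d.to_numpy())
    return np.hstack(parts)


def residualize_methylation(
    m: pd.DataFrame,
    cells: pd.DataFrame,
    plate: pd.Series | None = None,
    position_row: pd.Series | None = None,
    position_col: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-CpG residuals on cell proportions + plate/position, re-centered.

    Label columns embedded in ``m`` are used when the corresponding series
    arguments are omitted.  Residuals have the CpG mean added back so the
    output remains beta-like; downstream regression slopes are unchanged.
    """
    values, labels = _split_labels(m)
    plate = labels["plate"] if plate is None and "plate" in labels else plate
    position_row = (
        labels["position_row"] if position_row is None and "position_row" in labels
        else position_row
    )
    position_col = (
        labels["position_col"] if position_col is None and "position_col" in labels
        else position_col
    )
    n = len(values)
    dummy = pd.Series(["_none"] * n, index=values.index)
    d = _nuisance_design(
        cells.loc[values.index],
        plate if plate is not None else dummy,
        position_row if position_row is not None else dummy,
        position_col if position_col is not None else dummy,
    )
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        raise CollinearityError(
            f"nuisance design rank {rank} < {d.shape[1]} columns"
        )
    arr = values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(d, arr, rcond=None)
    resid = arr - d @ coef
    resid += arr.mean(axis=0)  # re-center at the CpG mean
    out = pd.DataFrame(resid, index=values.index, columns=values.columns)
    return pd.concat([labels, out], axis=1)


def remove_outcome_outliers(
    values: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """NaN-out values outside [Q1 - 3*IQR, Q3 + 3*IQR]; return exclusions.

    Unlike methylation winsorization, outcome outliers are *removed*.
    Returns the filtered series and an audit table (participant, value,
    reason).
    """
    obs = values.dropna()
    if len(obs) < 4:
        raise DegenerateInputError("need >= 4 observed values")
    lo, hi = _fences(obs.to_numpy(dtype=float))
    outside = (values < lo) | (values > hi)
    audit = pd.DataFrame(
        {
            "participant_id": values.index[outside],
            "value": values[outside].to_numpy(),
            "reason": [
                f"outside_3iqr_fence[{lo:.6g},{hi:.6g}]"
            ] * int(outside.sum()),
        }
    )
    return values.where(~outside), audit


def adjust_medication(
    outcome: str, values: pd.Series, flags: pd.DataFrame
) -> pd.DataFrame:
    """Medication adjustment; returns raw/adjusted values and exclusion flags.

    ``flags`` must carry boolean-ish columns ``antihypertensive_med``,
    ``statin_med``, ``diabetes_med`` aligned to ``values``.  Rules:
    SBP +15 and DBP +10 mm Hg under antihypertensives; LDL-C / 0.7 and
    TC / 0.8 under statins; HDL-C and TG untouched; glucose rows on
    diabetes medication are flagged excluded (never adjusted).
    """
    if outcome not in OUTCOMES:
        raise SchemaError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    out = pd.DataFrame({"raw": values})
    adjusted = values.astype(float).copy()
    excluded = pd.Series(False, index=values.index)
    reason = pd.Series("", index=values.index)

    if outcome == "SBP":
        on = flags["antihypertensive_med"].astype(bool)
        adjusted[on] = adjusted[on] + 15.0
    elif outcome == "DBP":
        on = flags["antihypertensive_med"].astype(bool)
        adjusted[on] = adjusted[on] + 10.0
    elif outcome == "LDL-C":
        on = flags["statin_med"].astype(bool)
        adjusted[on] = adjusted[on] / 0.7
    elif outcome == "TC":
        on = flags["statin_med"].astype(bool)
        adjusted[on] = adjusted[on] / 0.8
    elif outcome == "glucose":
        on = flags["diabetes_med"].astype(bool)
        excluded[on] = True
        reason[on] = "diabetes_medication"
        adjusted[on] = np.nan

    out["adjusted"] = adjusted
    out["excluded"] = excluded
    out["exclusion_reason"] = reason
    return out


def log_transform(outcome: str, values: pd.Series) -> pd.Series:
    """Natural log for glucose and CRP; identity otherwise."""
    if outcome not in OUTCOMES:
        raise SchemaError(f"unknown outcome {outcome!r}")
    if outcome not in LOG_OUTCOMES:
        return values
    bad = values.index[(values <= 0) & values.notna()]
    if len(bad):
        raise DomainError(
            f"nonpositive {outcome} values for participants {list(bad[:5])}"
        )
    return np.log(values)


def preprocess_methylation(
    m: pd.DataFrame, cells: pd.DataFrame
) -> pd.DataFrame:
    """impute -> winsorize -> residualize, in the fixed pipeline order."""
    return residualize_methylation(winsorize_matrix(mean_impute(m)), cells)


def preprocess_outcome(
    outcome: str, values: pd.Series, flags: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """outlier-remove -> medication-adjust -> transform, with audit trail.

    Returns the analysis-ready series (NaN where excluded) and an audit
    table of exclusions with machine-readable reasons.
    """
    kept, audit = remove_outcome_outliers(values)
    adj = adjust_medication(outcome, kept, flags)
    med_audit = pd.DataFrame(
        {
            "participant_id": adj.index[adj["excluded"]],
            "value": adj.loc[adj["excluded"], "raw"].to_numpy(),
            "reason": adj.loc[adj["excluded"], "exclusion_reason"].to_numpy(),
        }
    )
    final = log_transform(outcome, adj["adjusted"])
    audit = pd.concat([audit, med_audit], ignore_index=True)
    audit.insert(0, "outcome", outcome)
    return final, audit
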