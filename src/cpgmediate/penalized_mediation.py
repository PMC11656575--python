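"""Multivariable mediation over the scan-significant CpGs via de-biased LASSO.

The per-CpG scan fits each mediator marginally; correlated CpGs can
therefore share one causal signal.  Here the outcome model includes *all*
scan-significant CpGs jointly:

    Y = b0 + bX X + sum_j beta_j M_j + b_C' C + e

with an L1 penalty on the CpG coefficients only (exposure and covariates
are design variables, not selection targets, and stay unpenalized —
implemented exactly by projecting them out of Y and M first).  The LASSO
point estimates are then de-biased with the node-wise-regression
correction, restoring asymptotically normal per-CpG estimates, standard
errors and p-values.  The node-wise penalty is tied to the main penalty;
as the penalty approaches zero the node-wise precision estimate becomes
the exact Gram inverse and the de-biased estimator coincides with
multivariable OLS (the p << n oracle).

Each CpG's adjusted mediator-outcome p-value is then combined with its
exposure-mediator p-value in the same composite-null mixture MaxP test
used by the scan, followed by BH FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .mediation_scan import (
    NullProportions,
    bh_fdr,
    corrected_pvalues,
    estimate_null_proportions,
    proportion_mediated_single,
)

__all__ = [
    "debiased_lasso_outcome",
    "joint_mixture_test",
    "adjusted_proportion_mediated",
    "penalized_mediation",
]


class UnsupportedRegimeError(ValueError):
    """p >= n: screen mediators before the multivariable model."""


class CollinearityError(ValueError):
    pass


def _residualize(z: np.ndarray, d: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(d, z, rcond=None)
    return z - d @ coef


def _lasso_path_cv_1se(
    m: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> float:
    """Penalty by 10-fold CV with the 1-SE rule on seed-fixed folds."""
    n = len(y)
    alpha_max = np.max(np.abs(m.T @ y)) / n
    alphas = alpha_max * np.logspace(0, -3, 40)
    cv = KFold(n_folds, shuffle=True, random_state=seed)
    fit = LassoCV(alphas=alphas, cv=cv, fit_intercept=False,
                  max_iter=50_000).fit(m, y)
    mse = fit.mse_path_  # n_alphas x n_folds, alphas_ descending
    mean = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean))
    ok = np.where(mean <= mean[best] + se[best])[0]
    return float(fit.alphas_[ok.min()])  # largest qualifying penalty


def _nodewise_precision(
    m: np.ndarray, lam: float | None, seed: int = 0
) -> np.ndarray:
    """Node-wise-regression approximate precision matrix Theta.

    Row j is (e_j - gamma_j) / tau_j^2 where gamma_j solves the penalized
    regression of column j on the others, with the node-wise penalty
    chosen by per-node cross-validation when ``lam`` is None.  At lam = 0
    this is the exact inverse of the sample Gram matrix.
    """
    n, p = m.shape
    sigma = m.T @ m / n
    if (lam is not None and lam <= 0) or p == 1:
        return np.linalg.inv(sigma)
    theta = np.zeros((p, p))
    for j in range(p):
        others = np.delete(np.arange(p), j)
        if lam is None:
            cv = KFold(5, shuffle=True, random_state=seed + j)
            fit = LassoCV(cv=cv, fit_intercept=False, max_iter=50_000).fit(
                m[:, others], m[:, j]
            )
            lam_j = float(fit.alpha_)
        else:
            lam_j = lam
            fit = Lasso(alpha=lam_j, fit_intercept=False, max_iter=50_000).fit(
                m[:, others], m[:, j]
            )
        gamma = fit.coef_
        resid = m[:, j] - m[:, others] @ gamma
        tau2 = resid @ m[:, j] / n + lam_j * np.abs(gamma).sum()
        row = np.zeros(p)
        row[j] = 1.0
        row[others] = -gamma
        theta[j] = row / tau2
    return theta


def debiased_lasso_outcome(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    m_sel: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    lam: float | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """De-biased LASSO estimates of each selected CpG's outcome coefficient.

    Returns one row per CpG with ``beta_debiased``, ``se`` and the
    two-sided normal-approximation ``p_beta_adjusted``.  ``lam=None``
    selects the penalty by 10-fold cross-validation at the 1-SE rule on
    seed-fixed folds; ``lam=0`` gives the multivariable OLS fit.
    """
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    marr = m_sel.to_numpy(dtype=float)
    n, p = marr.shape
    if p >= n:
        raise UnsupportedRegimeError(
            f"{p} mediators for n={n}; screen (e.g. via the scan) first"
        )
    d = [np.ones(n), xv]
    if covariates is not None and covariates.shape[1]:
        d.extend(list(covariates.to_numpy(dtype=float).T))
    d = np.column_stack(d)
    q = d.shape[1]

    m_r = _residualize(marr, d)
    y_r = _residualize(yv, d)

    if p >= 2:
        corr = np.corrcoef(m_r, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        if np.nanmax(np.abs(corr)) > 1 - 1e-10:
            raise CollinearityError("mediator columns are (near-)duplicated")

    nodewise_lam = lam
    if lam is None:
        lam = _lasso_path_cv_1se(m_r, y_r, n_folds, seed)
    if lam <= 0:
        beta_lasso, *_ = np.linalg.lstsq(m_r, y_r, rcond=None)
        lam = 0.0
        nodewise_lam = 0.0
    else:
        beta_lasso = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000).fit(
            m_r, y_r
        ).coef_

    # nodewise_lam is None when the main penalty came from CV: the
    # node-wise penalties are then CV-selected per node as well.
    theta = _nodewise_precision(m_r, nodewise_lam, seed=seed)
    resid = y_r - m_r @ beta_lasso
    beta_de = beta_lasso + theta @ (m_r.T @ resid) / n

    s = int(np.sum(beta_lasso != 0))
    df = max(n - q - s, 1)
    sigma2 = float(resid @ resid) / df
    gram = m_r.T @ m_r / n
    var = sigma2 * np.einsum("ij,jk,ik->i", theta, gram, theta) / n
    se = np.sqrt(var)
    z = beta_de / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "cpg_id": list(m_sel.columns),
            "beta_debiased": beta_de,
            "se": se,
            "p_beta_adjusted": p,
            "lambda": lam,
        }
    )


def joint_mixture_test(
    p_alpha: np.ndarray,
    p_beta_adjusted: np.ndarray,
    props: NullProportions | None = None,
    lam: float = 0.5,
    min_reestimate: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite-null MaxP test on the selected set; returns (corrected, q).

    Null proportions are re-estimated on the selected set when it has at
    least ``min_reestimate`` CpGs; otherwise ``props`` (inherited from the
    genome-wide scan) must be supplied.
    """
    pa = np.asarray(p_alpha, dtype=float)
    pb = np.asarray(p_beta_adjusted, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("p-value vectors must align")
    if pa.size == 0:
        return np.array([]), np.array([])
    if pa.size >= min_reestimate:
        props = estimate_null_proportions(pa, pb, lam=lam)
    elif props is None:
        raise ValueError(
            "selected set too small to estimate null proportions; "
            "pass props inherited from the scan"
        )
    corrected = corrected_pvalues(np.maximum(pa, pb), props)
    return corrected, bh_fdr(corrected)


def adjusted_proportion_mediated(
    alpha_hat: float, beta_debiased: float, total_effect: float
) -> float:
    """Proportion mediated with the co-mediator-adjusted outcome coefficient."""
    return proportion_mediated_single(alpha_hat, beta_debiased, total_effect)


def penalized_mediation(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    m_sel: pd.DataFrame,
    scan_results: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    total_effect: float | None = None,
    scan_props: NullProportions | None = None,
    lam: float | None = None,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full multivariable stage for one outcome's scan-significant CpGs.

    ``scan_results`` provides per-CpG ``alpha_hat``/``p_alpha`` from the
    scan; ``m_sel`` holds the corresponding CpG columns.  Returns one row
    per selected CpG with the de-biased coefficient, the joint corrected
    p, BH q, significance at ``q_threshold`` and (when ``total_effect``
    is given) the adjusted proportion mediated.
    """
    if m_sel.shape[1] == 0:
        return pd.DataFrame(
            columns=["cpg_id", "alpha_hat", "p_alpha", "beta_debiased", "se",
                     "p_beta_adjusted", "corrected_p", "q_value", "significant"]
        )
    de = debiased_lasso_outcome(y, x, m_sel, covariates, lam=lam, seed=seed)
    scan_idx = scan_results.set_index("cpg_id")
    de["alpha_hat"] = scan_idx.loc[de["cpg_id"], "alpha_hat"].to_numpy()
    de["p_alpha"] = scan_idx.loc[de["cpg_id"], "p_alpha"].to_numpy()
    corrected, q = joint_mixture_test(
        de["p_alpha"].to_numpy(), de["p_beta_adjusted"].to_numpy(),
        props=scan_props,
    )
    de["corrected_p"] = corrected
    de["q_value"] = q
    de["significant"] = de["q_value"] < q_threshold
    if total_effect is not None:
        de["proportion_mediated_adjusted"] = [
            adjusted_proportion_mediated(a, b, total_effect)
            for a, b in zip(de["alpha_hat"], de["beta_debiased"])
        ]
    return de
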