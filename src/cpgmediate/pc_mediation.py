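"""Principal-component mediation of the identified CpG mediators.

Because neighboring CpGs are correlated, per-CpG mediation effects cannot
be summed.  The identified mediators are therefore reduced to their top
principal components — which are mutually uncorrelated — and each PC's
average causal mediation effect (ACME) is estimated by the product of
coefficients from two linear models (PC ~ X + C and Y ~ X + PC + C),
with percentile confidence intervals from a nonparametric bootstrap over
participants.  Under the linear no-interaction model the product
estimator equals the total-minus-direct difference estimator exactly.
The sum of proportion-mediated over *significant* PCs is reported as the
cumulative proportion, a lower bound on the overall mediation effect of
the CpG set.

CpG columns are centered and scaled to unit variance before the PCA
(beta-value variances differ by orders of magnitude); PC signs follow the
convention that the largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCMediationRow",
    "compute_mediator_pcs",
    "mediate_single_pc",
    "cumulative_mediation",
    "mediate_pcs",
]


class DimensionError(ValueError):
    pass


@dataclass
class PCMediationRow:
    pc_index: int
    variance_fraction: float
    acme: float
    ci_low: float
    ci_high: float
    total_effect: float
    direct_effect: float
    proportion_mediated: float
    significant: bool
    n_boot: int
    n_redrawn: int = 0


def compute_mediator_pcs(
    m_selected: pd.DataFrame, k: int, scale: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k PCA of the selected CpG matrix.

    Returns ``(scores, loadings, variance_fractions)`` where ``scores`` is
    n x k, ``loadings`` is p x k, and variance fractions are relative to
    the total variance of the (scaled) matrix.
    """
    arr = m_selected.to_numpy(dtype=float)
    n, p = arr.shape
    if not (1 <= k <= min(n - 1, p)):
        raise DimensionError(f"k={k} must be in [1, min(n-1, p)={min(n - 1, p)}]")
    arr = arr - arr.mean(axis=0)
    if scale:
        sd = arr.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise DimensionError("constant CpG column cannot be scaled")
        arr = arr / sd
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # Deterministic sign: largest-|loading| entry positive per component.
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    var_frac = s**2 / (s**2).sum()
    return u[:, :k] * s[:k], vt[:k].T, var_frac[:k]


def _ols(d: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(d, y, rcond=None)[0]


def _acme_total(
    x: np.ndarray, pc: np.ndarray, y: np.ndarray, c: np.ndarray | None
) -> tuple[float, float, float]:
    """Product-of-coefficients ACME, total and direct effects."""
    base = [np.ones_like(x), x]
    if c is not None and c.size:
        base.extend(list(c.T))
    d_med = np.column_stack(base)
    a = _ols(d_med, pc)[1]
    d_out = np.column_stack([d_med[:, :2], pc, d_med[:, 2:]])
    coef = _ols(d_out, y)
    direct, b = coef[1], coef[2]
    acme = a * b
    return float(acme), float(direct + acme), float(direct)


def mediate_single_pc(
    x: pd.Series | np.ndarray,
    pc_score: np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
    pc_index: int = 1,
    variance_fraction: float = np.nan,
) -> PCMediationRow:
    """Bootstrap mediation analysis of one methylation PC.

    Point estimates come from the full sample; the percentile CI and the
    significance call (CI excluding 0) come from resampling participants
    with replacement.  Degenerate resamples with constant exposure are
    redrawn and counted.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    pv = np.asarray(pc_score, dtype=float)
    c = covariates.to_numpy(dtype=float) if covariates is not None else None
    n = len(xv)
    if not (len(yv) == len(pv) == n):
        raise DimensionError("X, PC and Y must have equal length")

    acme, total, direct = _acme_total(xv, pv, yv, c)

    rng = np.random.Generator(np.random.Philox(key=[seed, 17]))
    boots = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(xv[idx]) > 0:
                break
            n_redrawn += 1
        boots[b] = _acme_total(
            xv[idx], pv[idx], yv[idx], c[idx] if c is not None else None
        )[0]
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return PCMediationRow(
        pc_index=pc_index,
        variance_fraction=float(variance_fraction),
        acme=acme,
        ci_low=float(lo),
        ci_high=float(hi),
        total_effect=total,
        direct_effect=direct,
        proportion_mediated=acme / total if total != 0 else np.nan,
        significant=bool(lo > 0 or hi < 0),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def cumulative_mediation(rows: list[PCMediationRow]) -> float:
    """Sum of proportion-mediated over PCs whose ACME CI excludes zero."""
    return float(
        sum(r.proportion_mediated for r in rows if r.significant)
    )


def mediate_pcs(
    x: pd.Series | np.ndarray,
    m_selected: pd.DataFrame,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    k: int | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    scale: bool = True,
) -> tuple[pd.DataFrame, float]:
    """PCA + per-PC bootstrap mediation + cumulative proportion.

    ``k`` defaults to 10 PCs, dropping to 5 when fewer than 10 CpGs are
    available (and never above min(n-1, p)).
    """
    n, p = m_selected.shape
    if k is None:
        k = 10 if p >= 10 else 5
    k = min(k, n - 1, p)
    scores, _loadings, var_frac = compute_mediator_pcs(m_selected, k, scale=scale)
    rows = [
        mediate_single_pc(
            x, scores[:, i], y, covariates,
            n_boot=n_boot, seed=seed + i, pc_index=i + 1,
            variance_fraction=var_frac[i],
        )
        for i in range(k)
    ]
    table = pd.DataFrame([r.__dict__ for r in rows])
    table["cumulative_proportion"] = (
        table["proportion_mediated"].where(table["significant"], 0.0).cumsum()
    )
    return table, cumulative_mediation(rows)
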