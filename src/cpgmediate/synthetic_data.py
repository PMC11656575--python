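"""Synthetic cohort generator for epigenome-wide mediation analysis.

Generates data with the statistical structure the analysis assumes: a
continuous standardized psychosocial-stress exposure, covariates, a
high-dimensional methylation (beta-value) mediator matrix under a known
composite-null mixture, and continuous outcomes with known direct and
mediated effects.  A truth table records each mediator's null category so
that error rates, power, and effect recovery can be evaluated downstream.

Mediators are generated on a latent Gaussian scale and clipped into
[0.001, 0.999] rather than logit-transformed, so the configured
exposure->mediator coefficient remains the linear-model coefficient except
in the (rare, reported) clipped tail.  Residuals are block-correlated with
exchangeable within-block correlation, emulating the local correlation of
CpGs on the array.  Cell-type proportions and plate/position assignments
add linear nuisance signal so that preprocessing residualization has a
real target to remove.

All randomness flows from a single counter-based (Philox) stream keyed by
``SimulationConfig.seed``, so every generated table is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_methylation",
    "generate_outcome",
    "generate_annotation",
    "NULL_CATEGORIES",
]

#: Composite-null category labels, indexed as (alpha status, beta status).
NULL_CATEGORIES = ("H00", "H10", "H01", "H11")

#: Default battery: measure -> (domain, number of items).  Twelve measures
#: across six stress domains (acute life events, financial, neighborhood,
#: relationship, discrimination, childhood adversity).
DEFAULT_BATTERY: dict[str, tuple[str, int]] = {
    "lifetime_traumas": ("acute_life_events", 7),
    "recent_life_events": ("acute_life_events", 6),
    "financial_strain": ("financial_stress", 2),
    "financial_autonomy": ("financial_stress", 2),
    "neighborhood": ("neighborhood_stress", 4),
    "spouse": ("relationship_stress", 4),
    "children": ("relationship_stress", 4),
    "family": ("relationship_stress", 4),
    "friends": ("relationship_stress", 4),
    "everyday_discrimination": ("lifetime_discrimination", 5),
    "major_discrimination": ("lifetime_discrimination", 6),
    "childhood_adversity": ("childhood_adversity", 4),
}

CELL_TYPE_NAMES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran", "Neu", "Eos")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig (or run config) is invalid."""


class DimensionError(ValueError):
    """Raised when input shapes do not conform."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``null_mix`` gives the proportions of mediators in the four composite
    categories (alpha=0 & beta=0, alpha!=0 & beta=0, alpha=0 & beta!=0,
    alpha!=0 & beta!=0), in that order.  ``alpha_effect`` is on the
    beta-value scale per SD of exposure; ``beta_effect`` is on the outcome
    scale per unit of beta-value.
    """

    n_participants: int = 500
    n_mediators: int = 2000
    null_mix: tuple[float, float, float, float] = (0.90, 0.045, 0.045, 0.01)
    alpha_effect: float = 0.05
    beta_effect: float = 10.0
    direct_effect: float = 1.0
    block_size: int = 10
    block_rho: float = 0.3
    n_cell_types: int = 6
    cell_effect_scale: float = 0.05
    n_plates: int = 8
    batch_effect_scale: float = 0.01
    noise_sd_mediator: float = 0.05
    noise_sd_outcome: float = 1.0
    exposure_age_corr: float = 0.2
    item_missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.n_mediators <= 0:
            raise ConfigurationError("n_mediators must be positive")
        mix = np.asarray(self.null_mix, dtype=float)
        if mix.shape != (4,):
            raise ConfigurationError("null_mix must have four proportions")
        if (mix < 0).any():
            raise ConfigurationError("null_mix proportions must be >= 0")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ConfigurationError("null_mix must sum to 1 within 1e-12")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigurationError("block_rho must be in [0, 1)")
        if self.noise_sd_mediator <= 0 or self.noise_sd_outcome <= 0:
            raise ConfigurationError("noise SDs must be > 0")
        if not (0 <= self.item_missing_rate < 1):
            raise ConfigurationError("item_missing_rate must be in [0, 1)")
        if self.block_size <= 0:
            raise ConfigurationError("block_size must be positive")
        if not (2 <= self.n_cell_types <= len(CELL_TYPE_NAMES)):
            raise ConfigurationError(
                f"n_cell_types must be in [2, {len(CELL_TYPE_NAMES)}]"
            )
        if self.n_plates <= 0:
            raise ConfigurationError("n_plates must be positive")
        if not (-1.0 < self.exposure_age_corr < 1.0):
            raise ConfigurationError("exposure_age_corr must be in (-1, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Counter-based generator; ``stream`` keys independent substreams."""
        return np.random.Generator(np.random.Philox(key=[self.seed, stream]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["null_mix"] = list(self.null_mix)
        return d


# ---------------------------------------------------------------------------
# Cohort: covariates and stress items
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the participant phenotype table and the stress-item table.

    The phenotype table carries age, sex, education, smoking, fasting,
    medication flags, measurement year, and ten synthetic ancestry PCs,
    plus the latent standardized exposure (column ``exposure_true``) from
    which the stress items were built.  Stress items are continuous
    responses whose measure/domain roll-up recovers an exposure strongly
    correlated with ``exposure_true``; a configurable fraction of items is
    missing at random so the completeness rule downstream has bite.
    """
    n = config.n_participants
    rng = config.rng(stream=1)

    x = rng.standard_normal(n)  # latent exposure, SD 1
    ids = [f"P{i:06d}" for i in range(1, n + 1)]

    rho = config.exposure_age_corr
    age = 70.4 + 9.5 * (rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    pheno = pd.DataFrame(
        {
            "participant_id": ids,
            "age": np.round(age, 1),
            "sex": rng.choice(["Female", "Male"], size=n, p=[0.59, 0.41]),
            "education": rng.choice(
                ["no_degree", "hs_degree", "college_or_higher"],
                size=n,
                p=[0.13, 0.60, 0.27],
            ),
            "smoking": rng.choice(
                ["never", "former", "current"], size=n, p=[0.45, 0.43, 0.12]
            ),
            "measurement_year": rng.choice([2010, 2012], size=n),
            "fasting": rng.binomial(1, 0.8, size=n),
            "antihypertensive_med": rng.binomial(1, 0.57, size=n),
            "statin_med": rng.binomial(1, 0.50, size=n),
            "diabetes_med": rng.binomial(1, 0.21, size=n),
        }
    )
    for k in range(1, 11):
        pheno[f"ancestry_pc{k}"] = rng.standard_normal(n)
    pheno["exposure_true"] = x

    # Stress items: domain latent -> measure latent -> items, each step
    # diluting the exposure signal so items look survey-like but the
    # standardized roll-up tracks x.
    domains = sorted({d for d, _ in DEFAULT_BATTERY.values()})
    domain_latent = {
        d: np.sqrt(0.7) * x + np.sqrt(0.3) * rng.standard_normal(n) for d in domains
    }
    item_cols: dict[str, np.ndarray] = {}
    for measure, (domain, n_items) in DEFAULT_BATTERY.items():
        mlat = np.sqrt(0.8) * domain_latent[domain] + np.sqrt(0.2) * rng.standard_normal(n)
        for k in range(1, n_items + 1):
            vals = mlat + 0.7 * rng.standard_normal(n)
            if config.item_missing_rate > 0:
                miss = rng.random(n) < config.item_missing_rate
                vals = np.where(miss, np.nan, vals)
            item_cols[f"{measure}__i{k}"] = np.round(vals, 4)
    items = pd.DataFrame({"participant_id": ids, **item_cols})
    return pheno, items


# ---------------------------------------------------------------------------
# Mediators: methylation beta values under the composite-null mixture
# ---------------------------------------------------------------------------

def generate_methylation(
    config: SimulationConfig, exposure: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the beta matrix, cell proportions and the per-CpG truth table.

    Returns ``(methylation, cells, truth)``.  ``methylation`` is
    participants x CpGs with ``plate``, ``position_row`` and
    ``position_col`` columns prepended; ``cells`` holds Dirichlet
    cell-type proportions summing to one per participant; ``truth`` has
    one row per CpG with its null category and true alpha/beta.  The
    fraction of entries altered by clipping into [0.001, 0.999] is stored
    in ``truth.attrs["clip_rate"]``.
    """
    x = np.asarray(exposure, dtype=float)
    n, j = config.n_participants, config.n_mediators
    if x.shape != (n,):
        raise DimensionError(
            f"exposure has length {x.shape[0] if x.ndim == 1 else x.shape}, "
            f"expected {n}"
        )
    rng = config.rng(stream=2)

    cats = rng.choice(4, size=j, p=np.asarray(config.null_mix, dtype=float))
    alpha = np.where(np.isin(cats, (1, 3)), config.alpha_effect, 0.0)
    beta = np.where(np.isin(cats, (2, 3)), config.beta_effect, 0.0)

    cpg_ids = [f"cg{k:08d}" for k in range(j)]
    pids = [f"P{i:06d}" for i in range(1, n + 1)]

    mu = rng.uniform(0.2, 0.8, size=j)

    # Exchangeable block-correlated residuals: shared block factor + noise.
    n_blocks = -(-j // config.block_size)
    block_of = np.repeat(np.arange(n_blocks), config.block_size)[:j]
    rho = config.block_rho
    shared = rng.standard_normal((n, n_blocks))
    eps = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * rng.standard_normal((n, j))
    eps *= config.noise_sd_mediator

    # Cell proportions (Dirichlet, granulocyte-dominated) and their
    # per-CpG linear nuisance coefficients on the first K-1 cell types.
    k_cells = config.n_cell_types
    conc = np.array([5.0] * (k_cells - 1) + [20.0])
    cells_arr = rng.dirichlet(conc, size=n)
    cell_names = list(CELL_TYPE_NAMES[: k_cells - 1]) + ["Gran"]
    cell_coef = rng.normal(0.0, config.cell_effect_scale, size=(k_cells - 1, j))
    cell_signal = (cells_arr[:, :-1] - cells_arr[:, :-1].mean(axis=0)) @ cell_coef

    # Plate and position batch effects (additive per-CpG shifts).
    plate = rng.integers(0, config.n_plates, size=n)
    pos_row = rng.integers(0, 8, size=n)
    pos_col = rng.integers(0, 12, size=n)
    plate_eff = rng.normal(0.0, config.batch_effect_scale, size=(config.n_plates, j))
    row_eff = rng.normal(0.0, config.batch_effect_scale / 2, size=(8, j))
    col_eff = rng.normal(0.0, config.batch_effect_scale / 2, size=(12, j))
    batch_signal = plate_eff[plate] + row_eff[pos_row] + col_eff[pos_col]

    latent = mu[None, :] + np.outer(x, alpha) + cell_signal + batch_signal + eps
    m = np.clip(latent, 0.001, 0.999)
    clip_rate = float(np.mean(m != latent))

    meth = pd.DataFrame(m, index=pd.Index(pids, name="participant_id"), columns=cpg_ids)
    meth.insert(0, "plate", [f"plate{p + 1}" for p in plate])
    meth.insert(1, "position_row", [f"R{r + 1}" for r in pos_row])
    meth.insert(2, "position_col", [f"C{c + 1}" for c in pos_col])

    cells = pd.DataFrame(
        cells_arr, index=pd.Index(pids, name="participant_id"), columns=cell_names
    )

    truth = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "null_category": [NULL_CATEGORIES[c] for c in cats],
            "true_alpha": alpha,
            "true_beta": beta,
            "true_mediation_effect": alpha * beta,
        }
    )
    truth.attrs["clip_rate"] = clip_rate
    return meth, cells, truth


# ---------------------------------------------------------------------------
# Outcome
# ---------------------------------------------------------------------------

def generate_outcome(
    config: SimulationConfig,
    exposure: Sequence[float],
    methylation: pd.DataFrame,
    truth: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_effects: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw Y = direct_effect * X + sum_j beta_j * M_j (+ C effects) + noise.

    ``methylation`` may include the plate/position label columns, which are
    ignored.  ``covariates``/``covariate_effects`` optionally add linear
    covariate terms (columns are standardized first, so effects are per SD).
    """
    x = np.asarray(exposure, dtype=float)
    n = config.n_participants
    if x.shape != (n,):
        raise DimensionError("exposure length mismatch")
    mcols = [c for c in methylation.columns if c not in ("plate", "position_row", "position_col")]
    if list(truth["cpg_id"]) != mcols:
        raise DimensionError("truth table does not match methylation columns")
    m = methylation[mcols].to_numpy(dtype=float)
    if m.shape != (n, len(mcols)):
        raise DimensionError("methylation shape mismatch")

    rng = config.rng(stream=3)
    y = config.direct_effect * x + m @ truth["true_beta"].to_numpy(dtype=float)
    if covariates is not None:
        c = covariates.to_numpy(dtype=float)
        effs = np.asarray(covariate_effects, dtype=float)
        if c.shape[0] != n or effs.shape != (c.shape[1],):
            raise DimensionError("covariate/effect shape mismatch")
        c = (c - c.mean(axis=0)) / c.std(axis=0, ddof=1)
        y = y + c @ effs
    y = y + config.noise_sd_outcome * rng.standard_normal(n)
    return y


# ---------------------------------------------------------------------------
# Annotation (for enrichment testing)
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimulationConfig,
    enriched_cpgs: Sequence[str] = (),
    enhancer_rate: float = 0.15,
    dhs_rate: float = 0.20,
    eqtm_rate: float = 0.046,
    enrichment_odds: float = 5.0,
) -> pd.DataFrame:
    """Synthetic BED-like CpG annotation table.

    Produces chromosome, position, proximal gene, signed TSS distance
    (upstream negative), CGI distance, enhancer/DHS flags and an eQTM
    flag.  CpGs named in ``enriched_cpgs`` get their enhancer and eQTM
    odds multiplied by ``enrichment_odds`` so enrichment tests have a
    known signal.  Purely artifact plumbing; mirrors no real manifest.
    """
    j = config.n_mediators
    rng = config.rng(stream=4)
    cpg_ids = [f"cg{k:08d}" for k in range(j)]
    enriched = np.isin(np.array(cpg_ids), np.asarray(list(enriched_cpgs)))

    def flip(base_rate: float) -> np.ndarray:
        odds = base_rate / (1 - base_rate)
        p = np.where(
            enriched, odds * enrichment_odds / (1 + odds * enrichment_odds), base_rate
        )
        return rng.random(j) < p

    chrom = rng.integers(1, 23, size=j)
    pos = rng.integers(10_000, 248_000_000, size=j)
    # TSS distance: mix of upstream-promoter-like and distal.
    tss = np.where(
        rng.random(j) < 0.3,
        -rng.integers(0, 5000, size=j),
        rng.integers(1, 100_000, size=j),
    )
    # CGI distance: 0 (in island), shore/shelf range, or far.
    u = rng.random(j)
    cgi = np.where(u < 0.3, 0, np.where(u < 0.55, rng.integers(1, 4001, size=j),
                                        rng.integers(4001, 100_000, size=j)))
    ann = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "gene": [f"GENE{g:05d}" for g in rng.integers(0, 20000, size=j)],
            "tss_distance": tss,
            "cgi_distance": cgi,
            "enhancer": flip(enhancer_rate).astype(int),
            "dhs": flip(dhs_rate).astype(int),
            "eqtm": flip(eqtm_rate).astype(int),
        }
    )
    return ann
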