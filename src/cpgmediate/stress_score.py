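"""Cumulative psychosocial-stress scoring.

Item-level survey responses are rolled up in three stages:

1. *Measure*: a participant's measure score is the mean of answered items
   rescaled to the full item count (proration), provided at least 80% of
   the measure's items were answered; otherwise the measure is missing.
2. *Domain*: each measure score is z-standardized; a domain score is the
   standardized sum of its constituent measure z-scores.
3. *Cumulative*: the six domain z-scores are summed and re-standardized,
   yielding the exposure X (mean 0, SD 1 over the complete-case sample).

Participants missing any measure are excluded (complete-case rule), so
the final score table contains exactly the intersection of per-measure
complete sets.  Sample SD (n-1 denominator) is used throughout.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import DEFAULT_BATTERY, ConfigurationError

__all__ = [
    "score_measure",
    "standardize",
    "aggregate_domain",
    "cumulative_score",
    "score_battery",
    "load_battery",
    "DEFAULT_BATTERY",
]


class SchemaError(KeyError):
    """Raised when a table does not match the configured battery."""


class DegenerateInputError(ValueError):
    """Raised when a vector cannot be standardized (zero spread)."""


def load_battery(path: str) -> dict[str, tuple[str, int]]:
    """Read a battery definition (measure -> domain, n_items) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    battery = {}
    for measure, entry in raw.items():
        battery[measure] = (str(entry["domain"]), int(entry["n_items"]))
    return battery


def score_measure(
    items: pd.DataFrame, n_items: int, completeness_threshold: float = 0.8
) -> pd.Series:
    """Prorated raw score for one measure; missing below the completeness bar.

    ``items`` holds one column per item.  Participants answering at least
    ``completeness_threshold`` of the items get ``mean(answered) * n_items``
    (the mean-of-answered score rescaled to the full item count); others
    get NaN.
    """
    if not (0.0 < completeness_threshold <= 1.0):
        raise ConfigurationError("completeness_threshold must be in (0, 1]")
    if items.shape[1] != n_items:
        raise SchemaError(
            f"expected {n_items} item columns, got {items.shape[1]}"
        )
    answered = items.notna().sum(axis=1)
    frac = answered / n_items
    score = items.mean(axis=1) * n_items
    return score.where(frac >= completeness_threshold)


def standardize(values: pd.Series) -> pd.Series:
    """(v - mean) / SD over non-missing entries; NaN propagated."""
    obs = values.dropna()
    if len(obs) < 2:
        raise DegenerateInputError("need >= 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero or undefined SD")
    return (values - obs.mean()) / sd


def aggregate_domain(measure_z: pd.DataFrame) -> pd.Series:
    """Standardized sum of a domain's measure z-scores (complete cases only)."""
    total = measure_z.sum(axis=1, skipna=False)  # any missing measure -> NaN
    return standardize(total)


def cumulative_score(domain_z: pd.DataFrame, n_domains: int = 6) -> pd.Series:
    """Standardized sum of the domain z-scores: the exposure X."""
    if domain_z.shape[1] != n_domains:
        raise ConfigurationError(
            f"expected {n_domains} domains, got {domain_z.shape[1]}"
        )
    total = domain_z.sum(axis=1, skipna=False)
    return standardize(total)


def score_battery(
    item_table: pd.DataFrame,
    battery: Mapping[str, tuple[str, int]] = DEFAULT_BATTERY,
    completeness_threshold: float = 0.8,
) -> pd.DataFrame:
    """Full roll-up: items -> measure z -> domain z -> cumulative score.

    ``item_table`` is wide with a ``participant_id`` column and item
    columns named ``<measure>__i<k>``.  Returns a table indexed by
    participant ID with ``z_<measure>``, ``z_domain_<domain>`` and
    ``cumulative_stress`` columns, restricted to participants passing the
    completeness rule on every measure (complete cases).  Standardization
    is performed over the complete-case set, so each standardized column
    has mean 0 and SD 1 there.
    """
    df = item_table.set_index("participant_id")
    raw_scores = {}
    for measure, (_domain, n_items) in battery.items():
        cols = [f"{measure}__i{k}" for k in range(1, n_items + 1)]
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"measure {measure!r} missing items {missing_cols}")
        raw_scores[measure] = score_measure(
            df[cols], n_items, completeness_threshold
        )
    raw = pd.DataFrame(raw_scores)

    complete = raw.dropna().index  # complete-case rule across all measures
    raw = raw.loc[complete]

    measure_z = pd.DataFrame(
        {m: standardize(raw[m]) for m in battery}, index=complete
    )
    domains: dict[str, list[str]] = {}
    for measure, (domain, _n) in battery.items():
        domains.setdefault(domain, []).append(measure)
    domain_z = pd.DataFrame(
        {d: aggregate_domain(measure_z[ms]) for d, ms in domains.items()},
        index=complete,
    )
    out = pd.concat(
        [
            measure_z.add_prefix("z_"),
            domain_z.add_prefix("z_domain_"),
        ],
        axis=1,
    )
    out["cumulative_stress"] = cumulative_score(domain_z, n_domains=len(domains))
    return out


def write_battery(battery: Mapping[str, tuple[str, int]], path: str) -> None:
    """Write a battery definition to YAML (inverse of :func:`load_battery`)."""
    raw = {m: {"domain": d, "n_items": n} for m, (d, n) in battery.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
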