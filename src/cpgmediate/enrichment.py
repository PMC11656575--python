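"""Genomic-feature and eQTM enrichment of mediating CpGs.

Mediating CpGs are compared against the non-mediating background with
two-sided Fisher's exact tests (minimum-likelihood convention: the
two-sided p sums all tables, with the observed margins, whose probability
does not exceed the observed table's).  Feature flags are derived from
distances: a CpG is a *promoter* CpG if it lies less than 1.5 kb upstream
of a transcription start site (signed TSS distance in (-1500, 0], with
upstream negative); it is in a CGI *shore* if within 2 kb of a CpG island
and in a *shelf* if between 2 and 4 kb; distance 0 means inside the
island itself.  Enhancer, DHS and eQTM membership are consumed as
user-supplied boolean annotation columns.

Odds ratios are the sample cross-product (a*d)/(b*c); when a cell is zero
the Haldane-Anscombe 0.5 correction is applied to the displayed OR only
(flagged), never to the exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "derive_feature_flags",
    "fisher_enrichment",
    "eqtm_enrichment",
    "enrichment_table",
    "FEATURES",
]

#: Feature columns tested by default, in reporting order.
FEATURES = ("dhs", "enhancer", "promoter", "shore_shelf", "cgi", "eqtm")


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is empty."""


@dataclass
class EnrichmentResult:
    feature: str
    mediator_with: int       # a
    mediator_without: int    # b
    background_with: int     # c
    background_without: int  # d
    odds_ratio: float
    p_value: float
    haldane_corrected: bool


def derive_feature_flags(annotation: pd.DataFrame) -> pd.DataFrame:
    """Add promoter/cgi/shore/shelf flags from the distance columns.

    Missing distances yield missing flags (pandas NA), which are excluded
    from the corresponding feature's test.
    """
    ann = annotation.copy()
    tss = ann["tss_distance"]
    cgi = ann["cgi_distance"]
    ann["promoter"] = ((tss > -1500) & (tss <= 0)).astype("boolean")
    ann.loc[tss.isna(), "promoter"] = pd.NA
    ann["cgi"] = (cgi == 0).astype("boolean")
    ann["shore"] = ((cgi > 0) & (cgi <= 2000)).astype("boolean")
    ann["shelf"] = ((cgi > 2000) & (cgi <= 4000)).astype("boolean")
    for col in ("cgi", "shore", "shelf"):
        ann.loc[cgi.isna(), col] = pd.NA
    ann["shore_shelf"] = ann["shore"] | ann["shelf"]
    return ann


def fisher_enrichment(
    mediator_flags: pd.Series | np.ndarray,
    background_flags: pd.Series | np.ndarray,
    feature: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of feature membership, mediators vs
    background.  Missing flags are dropped before counting."""
    mf = pd.Series(mediator_flags).dropna().astype(bool)
    bf = pd.Series(background_flags).dropna().astype(bool)
    if mf.empty or bf.empty:
        raise DegenerateTableError("both groups must be non-empty")
    a, b = int(mf.sum()), int((~mf).sum())
    c, d = int(bf.sum()), int((~bf).sum())
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(f"empty feature margin: {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    haldane = min(a, b, c, d) == 0
    if haldane:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return EnrichmentResult(
        feature=feature,
        mediator_with=a, mediator_without=b,
        background_with=c, background_without=d,
        odds_ratio=float(orr), p_value=float(p),
        haldane_corrected=haldane,
    )


def eqtm_enrichment(
    mediator_cpgs: pd.Index | list[str], annotation: pd.DataFrame
) -> EnrichmentResult:
    """Fisher test on the eQTM flag, mediating vs non-mediating CpGs."""
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    is_med = ann.index.isin(mediator_cpgs)
    return fisher_enrichment(
        ann.loc[is_med, "eqtm"], ann.loc[~is_med, "eqtm"], feature="eqtm"
    )


def enrichment_table(
    mediator_cpgs: pd.Index | list[str],
    annotation: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
) -> pd.DataFrame:
    """One Fisher test per feature; mediators vs all other annotated CpGs."""
    ann = derive_feature_flags(annotation)
    ann = ann.set_index("cpg_id") if "cpg_id" in ann.columns else ann
    is_med = ann.index.isin(mediator_cpgs)
    rows = []
    for feat in features:
        res = fisher_enrichment(
            ann.loc[is_med, feat], ann.loc[~is_med, feat], feature=feat
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
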