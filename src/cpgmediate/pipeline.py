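"""End-to-end orchestration with a single config, fixed seeds and an audit trail.

Stage order: stress scoring -> methylation & outcome preprocessing ->
total effects -> (gated on Model-1 p < 0.05) epigenome-wide mediation
scan -> PC mediation -> de-biased LASSO mediation -> enrichment.  Every
run writes per-stage TSVs, an exclusions audit file (participant/CpG,
stage, machine-readable reason) and a JSON manifest whose row counts
reconcile at every stage (input = analyzed + excluded).  Re-running with
the same config reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing, total_effects
from .mediation_scan import mediation_scan
from .pc_mediation import mediate_pcs
from .penalized_mediation import penalized_mediation
from .enrichment import enrichment_table
from .stress_score import score_battery
from .synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    generate_annotation,
    generate_cohort,
    generate_methylation,
    generate_outcome,
)

logger = logging.getLogger("cpgmediate")

__all__ = ["RunConfig", "run_pipeline", "simulate_study", "load_run_config"]

_TSV = dict(sep="\t", float_format="%.10g")


@dataclass
class RunConfig:
    out_dir: str
    phenotype: str
    stress_items: str
    methylation: str
    cells: str
    annotation: str | None = None
    outcomes: list[str] = field(default_factory=lambda: ["BMI"])
    model: int = 1
    gate_p: float = 0.05
    q_threshold: float = 0.05
    n_boot: int = 1000
    k_pcs: int | None = None
    lam: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gate_p < 1.0) or not (0.0 < self.q_threshold < 1.0):
            raise ConfigurationError("thresholds must be in (0, 1)")
        if self.model not in (1, 2):
            raise ConfigurationError("model must be 1 or 2")
        for attr in ("phenotype", "stress_items", "methylation", "cells"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise ConfigurationError(f"{attr} file not found: {p}")
        if self.annotation is not None and not Path(self.annotation).exists():
            raise ConfigurationError(f"annotation file not found: {self.annotation}")


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _read(path: str, index_col: str | None = "participant_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None and index_col in df.columns:
        df = df.set_index(index_col)
    return df


def simulate_study(
    sim: SimulationConfig, out_dir: str, outcomes: list[str] | None = None
) -> dict[str, str]:
    """Generate a full synthetic study and write its tables as TSV.

    Each requested outcome gets an independent noise draw (seeded from the
    base seed) but shares the exposure, mediators and truth table, so a
    single methylation matrix serves all outcomes.  Returns the map of
    written file paths.
    """
    outcomes = outcomes or ["BMI"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pheno, items = generate_cohort(sim)
    x = pheno["exposure_true"].to_numpy()
    meth, cells, truth = generate_methylation(sim, x)
    for i, name in enumerate(outcomes):
        cfg_i = dataclasses.replace(sim, seed=(sim.seed + 7919 * (i + 1)) % (2**31))
        pheno[name] = generate_outcome(cfg_i, x, meth, truth)
    ann = generate_annotation(sim)

    paths = {}
    for name, df, idx in (
        ("phenotype", pheno, False),
        ("stress_items", items, False),
        ("methylation", meth, True),
        ("cells", cells, True),
        ("truth", truth, False),
        ("annotation", ann, False),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, index=idx, **_TSV)
        paths[name] = str(p)
    cfg_path = out / "simulation_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump({"simulation": sim.to_dict(), "outcomes": outcomes}, fh,
                       sort_keys=True)
    paths["config"] = str(cfg_path)
    truth.attrs and logger.info(
        "clip rate: %.4g", truth.attrs.get("clip_rate", float("nan"))
    )
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit_rows: list[dict] = []
    manifest: dict = {
        "config": {**dataclasses.asdict(config)},
        "stages": {},
        "outcomes": {},
    }

    pheno = _read(config.phenotype)
    items = _read(config.stress_items, index_col=None)
    meth = _read(config.methylation)
    cells = _read(config.cells)
    ann = _read(config.annotation, index_col=None) if config.annotation else None

    # --- stress scoring (complete-case rule) -----------------------------
    scores = score_battery(items)
    scored_ids = scores.index.intersection(meth.index).intersection(pheno.index)
    for pid in pheno.index.difference(scores.index):
        audit_rows.append(
            {"stage": "stress_score", "unit": pid, "reason": "incomplete_stress_measure"}
        )
    scores = scores.loc[scored_ids]
    scores.to_csv(out / "stress_scores.tsv", **_TSV)
    manifest["stages"]["stress_score"] = {
        "n_input": int(len(pheno)),
        "n_analyzed": int(len(scored_ids)),
        "n_excluded": int(len(pheno) - len(scored_ids)),
    }

    # --- methylation preprocessing ---------------------------------------
    meth_a = meth.loc[scored_ids]
    meth_pp = preprocessing.preprocess_methylation(meth_a, cells.loc[scored_ids])
    mcols = [c for c in meth_pp.columns
             if c not in ("plate", "position_row", "position_col")]
    meth_pp.to_csv(out / "methylation_preprocessed.tsv", **_TSV)
    manifest["stages"]["preprocessing"] = {
        "n_participants": int(len(meth_pp)),
        "n_cpgs": int(len(mcols)),
    }

    x = scores["cumulative_stress"]
    pheno_a = pheno.loc[scored_ids]
    flags = pheno_a[["antihypertensive_med", "statin_med", "diabetes_med"]]

    te_rows = []
    for outcome in config.outcomes:
        y_raw = pheno_a[outcome]
        n_missing = int(y_raw.isna().sum())
        y, audit = preprocessing.preprocess_outcome(outcome, y_raw, flags)
        for _, r in audit.iterrows():
            audit_rows.append(
                {"stage": f"outcome:{outcome}", "unit": r["participant_id"],
                 "reason": r["reason"]}
            )
        for pid in y_raw.index[y_raw.isna()]:
            audit_rows.append(
                {"stage": f"outcome:{outcome}", "unit": pid, "reason": "missing_value"}
            )
        rows = y.notna()
        cov = total_effects.build_covariates(
            pheno_a.loc[rows],
            include_smoking=(config.model == 2),
            include_fasting=outcome in total_effects.FASTING_OUTCOMES,
        )
        te = total_effects.fit_total_effect(
            y[rows], x[rows], cov, outcome=outcome, model=config.model
        )
        te_rows.append(te.__dict__)
        gated = te.p_value < config.gate_p
        oman = {
            "n_available": int(len(y_raw)),
            "n_missing": n_missing,
            "n_excluded": int(len(audit)),
            "n_analyzed": int(rows.sum()),
            "total_effect": te.coef,
            "total_effect_p": te.p_value,
            "variance_explained": te.variance_explained,
            "passed_gate": bool(gated),
        }
        manifest["outcomes"][outcome] = oman
        if not gated:
            logger.info("outcome %s failed the Model-1 gate (p=%.3g)", outcome,
                        te.p_value)
            continue

        # --- epigenome-wide mediation scan -------------------------------
        scan, props = mediation_scan(
            x[rows], meth_pp.loc[rows.index[rows], mcols], y[rows], cov,
            total_effect=te.coef, q_threshold=config.q_threshold,
        )
        scan.to_csv(out / f"scan_{outcome}.tsv", index=False, **_TSV)
        sig = scan.loc[scan["significant"], "cpg_id"].tolist()
        for cid in scan.loc[scan["degenerate"], "cpg_id"]:
            audit_rows.append(
                {"stage": f"scan:{outcome}", "unit": cid, "reason": "degenerate_cpg"}
            )
        oman["scan"] = {
            "j_input": int(len(scan)),
            "j_degenerate": int(scan["degenerate"].sum()),
            "j_tested": int(len(scan) - scan["degenerate"].sum()),
            "n_significant": len(sig),
            "null_proportions": {
                "pi00": props.pi00, "pi10": props.pi10, "pi01": props.pi01,
            },
        }
        scan.loc[scan["significant"]].to_csv(
            out / f"hits_{outcome}.tsv", index=False, **_TSV
        )
        if not sig:
            continue

        # --- PC mediation -------------------------------------------------
        m_sel = meth_pp.loc[rows.index[rows], sig]
        pc_table, cumulative = mediate_pcs(
            x[rows], m_sel, y[rows], cov,
            k=config.k_pcs, n_boot=config.n_boot, seed=config.seed,
        )
        pc_table.to_csv(out / f"pc_mediation_{outcome}.tsv", index=False, **_TSV)
        oman["pc_mediation"] = {
            "k": int(len(pc_table)),
            "n_significant": int(pc_table["significant"].sum()),
            "cumulative_proportion": float(cumulative),
        }

        # --- de-biased LASSO mediation ------------------------------------
        pen = penalized_mediation(
            y[rows], x[rows], m_sel, scan, cov,
            total_effect=te.coef, scan_props=props,
            lam=config.lam, seed=config.seed, q_threshold=config.q_threshold,
        )
        pen.to_csv(out / f"lasso_mediation_{outcome}.tsv", index=False, **_TSV)
        oman["penalized_mediation"] = {
            "n_input": int(len(pen)),
            "n_significant": int(pen["significant"].sum()) if len(pen) else 0,
        }

        # --- enrichment ---------------------------------------------------
        if ann is not None:
            enr = enrichment_table(sig, ann)
            enr.to_csv(out / f"enrichment_{outcome}.tsv", index=False, **_TSV)
            oman["enrichment"] = {
                "n_features": int(len(enr)),
                "n_nominal": int((enr["p_value"] < 0.05).sum()),
            }

    pd.DataFrame(te_rows).to_csv(out / "total_effects.tsv", index=False, **_TSV)
    audit = pd.DataFrame(audit_rows, columns=["stage", "unit", "reason"])
    audit.to_csv(out / "audit.tsv", index=False, **_TSV)
    manifest["n_audit_rows"] = int(len(audit))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
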