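# cpgmediate

Epigenome-wide mediation analysis of cumulative psychosocial stress and
cardiometabolic risk factors.

Psychosocial stress is an established determinant of cardiometabolic
risk, and DNA methylation responds to both stress exposure and
cardiometabolic processes.  `cpgmediate` asks, CpG by CpG across the
epigenome, how much of the association between a cumulative stress score
X and a risk factor Y (BMI, waist circumference, blood pressure, lipids,
glucose, CRP) travels through methylation.  It is aimed at
epidemiologists and social-epigenomics researchers working with
survey + array cohorts, and ships a synthetic-data generator with a known
truth table so the entire pipeline is testable without restricted data.

## The model

For each CpG j the two mediation regressions are

    M_j = α₀ⱼ + αⱼ X + α_Cⱼᵀ C + ε_Mⱼ
    Y   = β₀ⱼ + β_Xⱼ X + βⱼ M_j + β_Cⱼᵀ C + ε_Yⱼ

with mediation effect αⱼ·βⱼ and proportion mediated αⱼβⱼ / total effect.
The null H₀ⱼ: αⱼβⱼ = 0 is *composite* — a mixture of (α=0, β=0),
(α=0, β≠0), (α≠0, β=0) — so the MaxP statistic max(p_αⱼ, p_βⱼ) is not
uniform under it.  The scan evaluates the corrected mixture reference

    P(MaxP ≤ t | H₀) = (π₀₁ t + π₁₀ t + π₀₀ t²) / (π₀₁ + π₁₀ + π₀₀)

with the component fractions estimated Storey-style from the two p-value
series, followed by Benjamini–Hochberg FDR (mediating CpG: q < 0.05).
Because correlated CpGs cannot have their effects summed, the
significant set is then (1) reduced to principal components, each PC's
average causal mediation effect (ACME) bootstrapped nonparametrically,
the cumulative proportion over significant PCs giving a lower bound on
the joint mediation effect; and (2) fit jointly with a de-biased LASSO
outcome model to find CpGs that remain mediators after adjusting for all
co-mediators.  Mediating CpGs are finally tested for enrichment in
genomic features (enhancer, promoter, DHS, CGI, shore/shelf) and eQTM
membership with two-sided Fisher exact tests.

See `docs/methods.md` for estimator details and design choices.

## Worked example

Simulate a cohort of 500 participants and 2,000 CpGs under the default
composite-null mixture (90% double null, 4.5% each single null, 1% true
mediators), then run every stage:

```python
import tempfile
from cpgmediate import SimulationConfig, simulate_study, RunConfig, run_pipeline

sim = SimulationConfig(n_participants=500, n_mediators=2000, seed=7,
                       alpha_effect=0.06, beta_effect=8.0,
                       null_mix=(0.90, 0.045, 0.045, 0.01))
d = tempfile.mkdtemp()
paths = simulate_study(sim, f"{d}/sim", outcomes=["BMI"])
cfg = RunConfig(out_dir=f"{d}/out", phenotype=paths["phenotype"],
                stress_items=paths["stress_items"],
                methylation=paths["methylation"], cells=paths["cells"],
                annotation=paths["annotation"], outcomes=["BMI"],
                n_boot=300, seed=1)
manifest = run_pipeline(cfg)
print(manifest["stages"]["stress_score"])
print(manifest["outcomes"]["BMI"]["scan"]["n_significant"])
print(manifest["outcomes"]["BMI"]["pc_mediation"])
```

prints (numbers from this exact run):

```
{'n_input': 500, 'n_analyzed': 441, 'n_excluded': 59}
102
{'k': 10, 'n_significant': 1, 'cumulative_proportion': 0.6037876748745992}
```

Reading: 59 of 500 simulated participants fail the 80% item-completeness
rule on at least one stress measure and are excluded (audited in
`out/audit.tsv`); the scan flags 102 CpGs at q < 0.05 — more than the 20
expected true mediators, because block-correlated CpGs that neighbor a
true mediator pick up its outcome signal, which is precisely why the PC
and LASSO stages exist; and the top-10 methylation PCs attribute ~60% of
the stress–BMI association to the identified CpG set.  Per-stage TSVs
(`scan_BMI.tsv`, `pc_mediation_BMI.tsv`, `lasso_mediation_BMI.tsv`,
`enrichment_BMI.tsv`), an exclusions audit and a JSON manifest with
reconciled row counts land in `out/`; re-running the same config
reproduces them byte for byte.

The same stages are available on the command line:

```bash
cpgmediate simulate --config sim.yaml --out study/
cpgmediate run-all --config run.yaml
# or stage by stage: preprocess, total-effects, scan, pc-mediate,
# lasso-mediate, enrich
```

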