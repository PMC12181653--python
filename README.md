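# clpnet

Cross-lagged panel network (CLPN) analysis of two-wave symptom
questionnaire data, built for studying longitudinal comorbidity among
complex post-traumatic stress (CPTSD), depression, and anxiety symptoms in
victimization cohorts.  It is aimed at researchers in psychiatric
epidemiology and network psychometrics who want a fully scripted,
reproducible version of the now-standard two-level workflow:

1. **Construct level** — a cross-lagged panel *path model* on composite
   scale scores (ITQ, PHQ-9, GAD-7): autoregressive and cross-lagged paths
   among the three constructs with gender/age covariates, maximum-likelihood
   fit indices (χ², CFI, TLI, RMSEA, SRMR) and Wald tests of path asymmetry
   (is CPTSD → anxiety stronger than anxiety → CPTSD?).
2. **Symptom level** — a directed *cross-lagged panel network* over the 28
   individual symptoms: for each wave-2 symptom *j*, an L1-penalized
   regression on all 28 wave-1 symptoms plus covariates,

   ```
   y_j(t2) = Σ_i B[i,j] · y_i(t1) + γ_j' z + ε_j,    penalty λ_j Σ_i |B[i,j]|
   ```

   with λ_j chosen per outcome by 10-fold cross-validation (one-SE rule by
   default).  Edge weight B[i,j] is the standardized prospective effect of
   symptom *i* on symptom *j* six months later.  Centrality is summarized
   by expected influence with autoregressive paths set to zero — Out-EI(i)
   = Σ_j B[i,j] (how much a symptom drives the rest of the network) and
   In-EI(j) = Σ_i B[i,j] (how much it is driven) — and estimation
   uncertainty by bootnet-style diagnostics: edge-weight bootstrap CIs and
   the case-dropping correlation-stability coefficient (CS > 0.25 moderate,
   CS > 0.5 very stable).

Because raw cohort data of this kind are rarely deposited, the package
ships a first-class synthetic-data generator: two-wave ordinal panels drawn
from a known directed truth network (latent Gaussian VAR(1) + quantile
discretization, victimization screening fields, control-question failures,
wave-1 missingness), which makes every pipeline stage testable and supports
parameter-recovery experiments.

## Worked example

Run the bundled 10-node demonstration (simulate → screen → impute → CLPN →
centrality → bootstrap stability):

```bash
clpnet all --config examples/demo_config.yaml
```

which prints (elapsed-time figures vary):

```
pipeline complete; outputs in demo_out
CS-coefficient (in_ei): 0.75 [very stable]
CS-coefficient (out_ei): 0.75 [very stable]
```

`demo_out/` then contains the analysis dataset, the full edge list
(`network_edges.csv`, with `cross_lagged` / `autoregressive` / `covariate`
rows), the display edge list thresholded at |weight| ≥ 0.05, a GraphML
export, the centrality table, edge bootstrap CIs, the stability curves and
a manifest with the config hash and seed.  In this demo the generator
plants 8 directed edges of weight ±0.4 among 10 symptoms; the estimated
network recovers them and the case-dropping bootstrap shows centralities
stay rank-stable (correlation ≥ 0.7 with 95% probability) even after
dropping 75% of participants — hence CS = 0.75.

The same stages are available as library calls (`simulate_panel`,
`apply_screening`, `impute_missing`, `estimate_network`,
`expected_influence`, `bootstrap_edges`, `case_drop_bootstrap`,
`fit_path_model`, ...) and as individual subcommands (`clpnet simulate |
screen | score | clpn | centrality | stability | panel`).

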