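# cea-nsclc

A decision-analytic cost-effectiveness model of first-line treatment for
EGFR-mutant advanced non-small-cell lung cancer (NSCLC) in the Chinese
health-care setting. It compares four strategies — pemetrexed–cisplatin
chemotherapy (PC), PC followed by pemetrexed maintenance, and gene-guided
gefitinib or icotinib — on ten-year discounted costs (2015 US$) and
quality-adjusted life-years, for health-economics researchers and
modellers who want a fully scripted, testable version of this analysis.

The pipeline:

- **Evidence synthesis** — frequentist random-effects network
  meta-analysis of trial-level PFS hazard ratios on the log scale
  (DerSimonian–Laird-type common τ², weighted least squares on the network
  design matrix).
- **Survival model** — Weibull PFS, `S(t) = exp(−λt^γ)` with λ = 0.1029,
  γ = 1.3077 for the control arm; treatment effects applied as
  `λ → λ·HR`; per-cycle transition probability
  `P(t) = 1 − exp[λ(t−1)^γ − λt^γ]`. A log–log least-squares fitter
  recovers (λ, γ, r²) from Kaplan–Meier curves.
- **Markov cohort engine** — three states (progression-free,
  post-progression, dead), 21-day cycles, 10-year horizon, 5%/year
  discounting, SAE costs/disutilities, salvage and supportive care,
  terminal care, EGFR-test amortisation, and Patient Assistance Program
  (PAP) drug-cost caps.
- **Analysis layer** — pairwise ICERs with frontier dominance labels,
  one-way (tornado) sensitivity analysis, 1,000-draw probabilistic
  sensitivity analysis, and cost-effectiveness acceptability curves at
  the $22,200/QALY threshold (3× 2015 Chinese per-capita GDP).

All model inputs (costs, utilities, probabilities, hazard ratios,
sampling distributions, one-way ranges) ship as a YAML parameter registry;
the six-trial evidence network ships as a CSV. See `docs/methods.md` for
the model's assumptions, conventions, and known reconciliation caveats
against the published analysis it re-implements.

## Worked example

```python
from cea_nsclc import build_default_registry, nma_estimate, default_network
from cea_nsclc.markov import ModelConfig, run_base_case
from cea_nsclc.cea import incremental_table

nma = nma_estimate(default_network())
print(f"icotinib vs PC: HR {nma.hr('icotinib'):.4f}, network I^2 {nma.i2:.1f}%")

reg = build_default_registry()
results = run_base_case(reg, ModelConfig())
print(incremental_table(list(results.values()), "control").round(3).to_string(index=False))
```

prints

```text
icotinib vs PC: HR 0.3953, network I^2 65.8%
   strategy      cost  pf_lys  overall_lys  qalys  delta_cost  delta_qalys       icer        dominance
    control 22371.411   0.302        0.971  0.569       0.000        0.000        NaN        reference
maintenance 35473.396   0.452        1.121  0.634   13101.986        0.065 200079.692 simple_dominated
  gefitinib 22168.001   0.530        1.199  0.775    -203.410        0.206   -986.253 simple_dominated
   icotinib 21766.689   0.609        1.278  0.840    -604.722        0.271  -2234.076      on_frontier
```

Reading it: the icotinib node's pooled hazard ratio versus PC is 0.3953
(the product of its two network edges, 0.67 × 0.59) amid moderate network
heterogeneity (I² ≈ 66%). In the base case, pemetrexed maintenance adds
0.065 QALYs at ~$13,100 extra (ICER ≈ $200k/QALY, far above the
threshold), while both TKIs deliver more QALYs for *less* money than
chemotherapy — negative incremental costs, so gefitinib is in turn
dominated by icotinib, which sits alone on the cost-effectiveness
frontier. Under the assistance-program caps (`pap=True`) the TKI costs
fall further.

The same analysis is available from the shell:

```sh
cea-nsclc run --out results/           # full pipeline + manifest
cea-nsclc base-case --pap              # strategy table with PAP caps
cea-nsclc tornado --strategy icotinib  # one-way sensitivity CSV
cea-nsclc psa --seed 1 --n-draws 1000  # probabilistic draws
```

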