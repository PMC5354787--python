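# Methods

## The decision problem

The package models the ten-year health and cost consequences of four
first-line strategies for advanced (stage IIIb/IV) non-small-cell lung
cancer harbouring an activating EGFR mutation, in the Chinese health-care
setting and in 2015 US dollars:

1. **control** — four 21-day cycles of pemetrexed–cisplatin (PC)
   chemotherapy;
2. **maintenance** — PC induction followed by single-agent pemetrexed until
   progression;
3. **gefitinib** — EGFR testing, then gefitinib 250 mg/day until
   progression;
4. **icotinib** — EGFR testing, then icotinib 375 mg/day until progression.

The primary output is the incremental cost-effectiveness ratio (ICER,
$/QALY) of each strategy against the control, judged against a
willingness-to-pay threshold of $22,200/QALY (3× 2015 Chinese per-capita
GDP).

## Evidence synthesis

No head-to-head trial covers all four strategies, so progression-free
survival (PFS) hazard ratios are synthesised over a six-study evidence
network with five nodes (PC; PC + pemetrexed maintenance; non-pemetrexed
platinum doublet; gefitinib; icotinib). The three gefitinib trials were run
against non-pemetrexed chemotherapy; a pemetrexed-doublet meta-analysis
edge (HR 0.90, 0.80–1.01) connects that comparator to PC, which is the only
way the network is connected.

Each trial's 95% CI is converted to a log-HR standard error as
`(ln hi − ln lo)/3.92`. The network is fitted by inverse-variance weighted
least squares on the design matrix of basic parameters (log-HR of each node
vs PC). A single between-study variance τ² is shared across the network,
estimated by the moment method from the fixed-effect network Q on
`df = n_studies − (n_nodes − 1) = 2`, with denominator
`tr(W) − tr((XᵀWX)⁻¹XᵀW²X)` — the network generalisation of the
DerSimonian–Laird estimator, to which it reduces exactly on a single
pairwise comparison (verified against R's `metafor` to 1e-6). Because the
network is loop-free, node estimates equal products of per-edge pooled HRs;
the tests exploit this as an independent oracle. The fitted surface:
icotinib vs PC HR 0.3953 (= 0.67 × 0.59, rounding to the published 0.40),
maintenance 0.59, gefitinib 0.457, I² = 65.8%.

The cohort engine uses the published pooled HRs (0.59/0.48/0.40) by
default, since those are the values the published base case was run with;
`RunConfig.hr_source="nma"` switches to the network estimates.

## Survival model

Control-arm PFS follows a Weibull model `S(t) = exp(−λ t^γ)` with λ =
0.1029, γ = 1.3077 (a published least-squares fit to the PARAMOUNT control
arm; r² = 0.981). The per-cycle progression probability is the conditional
`P(t) = 1 − S(t)/S(t−1)`. Treatment effects scale λ by the HR (shape
shared), the standard proportional-hazards Weibull adjustment.

The time unit of the printed parameters is not stated; the package defaults
to **21-day cycles** (`weibull_time_unit="cycle"`), which makes `P(t)`
directly consumable by the engine, with a `"month"` option. Under the cycle
convention the implied median PFS is 4.30 cycles (~3.0 months), which does
not equal the source trial's published 5.6-month median; the printed
parameters are nevertheless taken as given and never rescaled.

The package also ships the inverse operation, `fit_weibull`, a
least-squares fit of `ln(−ln S) = ln λ + γ ln t` to a Kaplan–Meier curve
reporting the linearised r². It exists so the curve-fitting stage is
testable: the synthetic-data module draws Weibull event times with
independent exponential censoring, builds the product-limit estimate
(via `lifelines`), and the fitter recovers the generating parameters
(exactly on noiseless curves; within 10% at n = 500 with 2%/time-unit
censoring).

## Markov cohort engine

Three states — progression-free (PFS), post-progression survival (PPS),
dead — over `floor(3650/21) = 173` cycles of 21 days. Everyone starts in
PFS. PFS exits only to PPS (no direct PFS→death path: the evidence provides
a PFS curve and a post-progression death probability, and overall survival
is their composition); PPS exits to death with a constant 0.086 per cycle
(implying a 7.7-cycle ≈ 5.3-month median post-progression survival,
matching the literature estimate it derives from). Costs and QALYs are
discounted at 5%/year as `1.05^(−cycle·21/365)`; life-years are reported
undiscounted (discounted variants are kept on the trace).

Per-cycle accrual while in PFS: scheduled drug cost (induction
pemetrexed 500 mg/m² at BSA 1.72 m² = 860 mg, billed as two whole 500-mg
vials, plus the $518.4 cisplatin/administration bundle; maintenance
pemetrexed or daily-priced TKI thereafter), SAE management cost
`507.4 × sae_prob(strategy)/sae_prob(control)` while on treatment, and
utility 0.82 less an SAE decrement `0.35 × sae_prob`. PPS cycles accrue
utility 0.58 and care costs: for the first `salvage_max_cycles` cycles
after progression 56.6% of progressors receive salvage chemotherapy
($2,352.7/cycle, the rest supportive care), then supportive care
($337.5/cycle) for everyone. Follow-up cost ($55.6/unit) is billed while
alive; terminal care ($2,042.91) is a one-off at death. Gene-guided
strategies pay the EGFR test up-front, amortised over the 47% mutation
prevalence ($380.95/0.47 = $810.5 per treated patient) — which is why
prevalence matters to a cohort that is 100% mutation-positive. Under the
Patient Assistance Program (scenario flag), cumulative TKI spending is
truncated at the cap ($11,538 gefitinib / $11,077 icotinib): full price
until the crossing cycle, a partial payment there, free drug after.

The PPS cohort is binned by cycles-since-progression (salvage-phase bins
plus an "older" bucket), so salvage duration is exact without an O(n²)
loop; occupancy conservation is asserted at every cycle to 1e-12.

### Accounting conventions and calibration

Several accrual conventions are under-determined by the published
description (follow-up billing frequency, salvage duration, SAE-disutility
duration, half-cycle correction, the Weibull time unit). Each is an
explicit `ModelConfig` flag. The shipped defaults were fixed once by
scanning the flag grid against the published control-strategy row (cost,
PF-LYs, overall LYs, QALYs) and freezing the best-fitting combination:

| flag | default | alternatives |
|---|---|---|
| `weibull_time_unit` | `cycle` | `month` |
| `half_cycle_correction` | on | off |
| `followup_per` | `month` (≈0.69 units/cycle) | `cycle` |
| `sae_disutility_mode` | `all_pfs` | `on_treatment`, `induction_only` |
| `salvage_max_cycles` | 8 | any ≥ 0 |

With these conventions the control row is: cost $22,371 (published
$22,127, 1.1% off), PF-LYs 0.302 (0.206), overall LYs 0.971 (1.058), QALYs
0.569 (0.513).

### Reconciliation caveat

The published summary table cannot be reproduced exactly from the
published inputs, under any convention: its control QALY is below the
utility-weighted value of its own life-year cells; its PF-LY ratios across
strategies are non-monotone in the stated HRs (impossible under the λ·HR
adjustment); and its post-progression LYs are inconsistent with the stated
0.086 per-cycle death probability. A faithful model therefore produces
larger TKI PFS/QALY gains than the published increments (≈0.27 vs 0.094
QALYs for icotinib), and — because the TKIs' longer PFS substitutes cheap
daily drug for expensive pemetrexed cycles — the TKIs come out *cheaper*
than control (icotinib simply dominates, ΔC ≈ −$600) where the publication
prints +$1,862 and an ICER of $19,809. The qualitative decision surface is
unaffected and is what the acceptance tests enforce: maintenance and
gefitinib dominated, icotinib on the frontier, ICER ordering icotinib <
gefitinib < maintenance, and PAP caps lowering both TKI ICERs. Two
downstream acceptance checks inherit the discrepancy and fail honestly:
the PSA probability of icotinib being cost-effective at $22,200/QALY is
~98–99% here (published ~90%) — a dominant strategy wins more draws — and
the tornado's widest spreads are the icotinib HR and drug price rather
than the published pemetrexed-cost/prevalence/PFS-utility triple, because
a near-zero ΔC makes the ICER hypersensitive to the HR range (0.19–0.81)
and insensitive to utilities.

## Sensitivity analyses

**One-way (tornado).** Every registry parameter with a non-degenerate
range is set to its bounds in turn and the pairwise ICER (default:
icotinib vs control) re-computed; entries are sorted by spread.
Parameters without published ranges carry ±25% of base; structural
constants (threshold, caps, discount rate, Weibull parameters) have
degenerate ranges and are not varied.

**Probabilistic.** 1,000 Monte-Carlo draws; beta for
probabilities/utilities, gamma (shape, scale — shape·scale reproduces
every printed base cost) for costs, normal for HRs as printed, truncated
to (0, 1] for probabilities and (0, ∞) for HRs/BSA by redraw. The Weibull
parameters and salvage uptake have no published distribution and stay
fixed; HR uncertainty carries the survival uncertainty. All four
strategies are evaluated on the same draw. Acceptability curves give each
strategy the fraction of draws with strictly maximal net monetary benefit
`λ·QALYs − cost` (ties split equally) on a $0–60,000 grid.

## Numerical and testing notes

- Registry audit: the published follow-up-cost gamma (437.5, 0.13) has
  mean 56.875 vs base 55.6 (2.3% off — the only inconsistent printed
  distribution); `validate_registry` reports rather than rejects it.
- The synthetic-data generators are pure functions of (spec, seed);
  simulated KM curves include right-censoring but not the digitisation
  error, informative censoring, or at-risk thinning of a real published
  curve, so passing recovery tests demonstrate estimator correctness, not
  robustness to those artefacts.
- DerSimonian–Laird intervals undercover with few trials (~87% at 3
  trials, ~91% at 10, vs nominal 95% — a known small-sample property);
  the coverage test asserts a band acknowledging this. The τ² moment
  estimator recovers a generating τ² = 0.05 to within ~9% on average over
  1,000 replicates.
- Problem sizes in the shipped tests/acceptance run: 173-cycle cohorts
  (exact, deterministic), 1,000 PSA draws, 1,000-replicate simulation
  checks; the full suite runs in well under a minute.
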