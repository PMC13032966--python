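# Methods

## Decision problem and structure

The package evaluates pharmacogenomic-guided capecitabine dosing in
metastatic breast cancer as a two-strategy decision problem. Under
*genotyping*, every patient is tested for reduced-function *DPYD* variants
before the first cycle (intermediate and poor metabolizers are pooled as
"variant", prevalence 6.3% at base case) and carriers start at 75% of the
standard dose; under *no genotyping* everyone starts at full dose. Dose
reduction is assumed not to compromise efficacy (progression and
post-progression mortality are dose-independent), so the trade-off is the
test price against avoided toxicity, hospitalization and treatment-related
death.

The cohort model is a discrete-time state-transition chain with a monthly
cycle. The progression-free compartment is expanded to genotype × dose
tier so that every transition probability is a function of the occupied
state alone:

* 6 progression-free states: {variant, wild type} × {100%, 75%, 50%};
* `Progressed` (treatment discontinued, no further toxicity or drug cost);
* 3 absorbing death states tagged by cause (background, treatment,
  progression). Disease-specific death occurs only from `Progressed`.

## Within-cycle event cascade

Events within a cycle are mutually exclusive for one cohort member and
resolve in a fixed conditional order: (1) background death; (2)
treatment-related death (progression-free only); (3) progression at
0.11/month, or death from progressed disease at 0.051/month; (4) grade 3/4
toxicity among surviving non-progressors. Destination probabilities are
products of the cascade terms, so every transition-matrix row sums to one
by construction. A toxicity event moves the survivor down one dose tier
from the next cycle (100% → 75% → 50%, floor absorbing) and is
hospitalized with a probability *conditional on the toxicity event* (0.4 /
0.54 / 0.6 for variant-standard, variant-reduced, wild-type-standard).
Treating those probabilities as conditional rather than as unconditional
monthly probabilities is a deliberate structural choice: unconditional
hospitalization of 40–60% of on-treatment patients every month would imply
monthly costs of several thousand dollars, an order of magnitude above the
total lifetime costs the model produces.

Cells of the genotype × tier grid without an observed anchor are filled by
proportionality: toxicity and treatment-death probabilities (and drug
cost) scale linearly with the dose fraction from the genotype's nearest
observed anchor (the 50% tier scales from the 75% anchor where one
exists, e.g. variant 50% toxicity = 0.044 × 50/75); hospitalization given
toxicity is a severity measure with no dose basis, so it reuses the
nearest anchor unscaled.

## Rewards, discounting, horizon

Rewards are booked on start-of-cycle occupancy at discount factor
`(1.03)^(−t/12)`; a member who dies during cycle *t* still accrues that
cycle's state rewards, and the microsimulation uses the identical
convention. No half-cycle correction is applied by default (a
`RunSettings` flag enables it for scenario analysis). The genotyping arm
pays the test cost once, at cycle 0, undiscounted.

Per cycle: QALYs = Σ occupancy·u(state)/12 − (toxicity events)·0.125/12 −
(hospitalizations)·0.28·(7/365.25); life-years = alive occupancy/12, also
discounted; cost = drug (monthly full-dose price $115.56 × tier fraction,
cross-checked against the 1,250 mg/m², BSA 1.8 m², 14-of-21-day regimen at
$0.64/500 mg prorated to a 30-day month) + $12,907 per hospitalization
(+ test). The toxicity disutility lasts one cycle per event; the
hospitalization disutility lasts one week and is additive on top of the
toxicity decrement (a flag disables the overlap). Disease-management and
end-of-life costs are equal across arms by assumption and therefore set to
zero — totals represent drug + test + hospitalization only. The horizon
runs from age 62 to age 100 (456 cycles) with early termination once live
occupancy falls below 1e−8; at base case this truncates at 347 cycles.

Treatment-related death applies in every on-treatment cycle. If the
published monthly probabilities are instead understood as risks confined
to the first cycles of therapy, a `treatment_death_max_cycles` flag
restricts them; this is the single input to which the incremental results
are most sensitive, because averted treatment deaths are the dominant
source of between-arm QALY/LY differences (all of which scale with the
6.3% carrier share).

## Background mortality

Rather than shipping an external life table, background mortality is a
two-parameter Gompertz law, `q(x) = 1 − exp(−a·e^{b(x−60)})` with
a = 0.0065, b = 0.085, chosen to approximate published US female annual
death probabilities over ages 60–90 (q(62) ≈ 0.008, q(85) ≈ 0.05). The
annual probability is converted to monthly by
`1 − (1−q)^{1/12}`; the cohort ages continuously from 62 with lookup at
integer age, clamped at the terminal row. Background mortality is a minor
force here (post-progression mortality is 0.051/month), so residual error
in the approximation has little leverage; `LifeTable.from_csv` accepts any
externally supplied table.

## Parameters and uncertainty

`ModelParameters` is a single validated record of all inputs (probabilities
in [0,1], utilities in [0,1], non-negative costs, strictly decreasing dose
fractions); YAML configs override fields by name and round-trip exactly.
Each uncertain parameter carries a distribution for probabilistic
analysis: Beta(α, β) for probabilities and utilities, Gamma parameterized
by (mean, sd) and moment-matched to shape/scale — the (mean, sd) reading
is the only one that centres the cost distributions on their point
estimates — and Triangular(min, max, mode) for the rare treatment-death
probabilities. Distribution means match the base-case values to within 2%
except two transcribed-as-published Betas (variant-standard toxicity,
+4.3%; variant-standard hospitalization, −2.9%), a self-consistency check
enforced in the test suite. Parameters without a published distribution
(discount rate, BSA, dose fractions, structural settings) stay fixed in
the PSA.

Deterministic analysis varies one parameter at a time over its published
range where one exists (variant prevalence 3–8%) and ±25% otherwise, with
the tornado ranking parameters by absolute ICER excursion (ties broken
alphabetically so the ordering is reproducible). The PSA draws all
distributions jointly and independently, evaluates *both* arms on each
draw (common draws — required for a meaningful incremental distribution),
and classifies draws by incremental NMB sign at $100,000/QALY;
"cost-saving" means strictly lower cost with strictly higher QALYs. Each
iteration samples from a substream spawned deterministically from the
run-level seed, so results are bit-reproducible and order-independent. No
correlation structure among parameters is modelled.

## Microsimulation oracle

`simulate_patients` draws individual trajectories with the same cascade
order, reward timing and discounting as the cohort engine — by
construction, so that disagreement isolates bugs rather than convention
mismatches. It emulates the event structure the cohort model assumes
(genotype draw, tiered dosing, toxicity/hospitalization, cause-tagged
exit) and nothing more: no between-patient heterogeneity beyond genotype,
no real-world treatment interruptions or efficacy effects of dose
reduction, so agreement validates the engine's bookkeeping, not the
model's clinical fidelity. The validation table reports z-scores of
microsimulation means against cohort expectations for cost, QALYs and
life-years per arm; the test suite runs 50,000–60,000 patients per arm
(Monte-Carlo standard errors near $16, 0.003 QALY, 0.006 LY) and requires
|z| ≤ 3, plus state-occupancy agreement at cycles 1, 6, 12 and 24 within
binomial error. The CLI default is 200,000 patients per arm.

## Numerical choices

* Transition matrices for all cycles are assembled vectorized as a
  (T, 10, 10) array (only background mortality varies by cycle);
  occupancy propagation is a sequential vector–matrix product. A full
  two-arm evaluation takes ~3 ms, so the 10,000-draw PSA (~20,000 cohort
  runs) completes in about half a minute on one CPU.
* Row sums are exact to 1e−12 and trace occupancy to 1e−10 by
  construction; these are asserted, not renormalized.
* Ties in the tornado ordering and the degenerate one-way range
  (low = high) are handled deterministically; ICERs are NaN when the QALY
  increment is exactly zero, with classification falling back to the NMB
  sign.
* The monthly cycle is prorated as 30 days for the drug-cost cross-check
  (configurable to 30.44).

## Known limitations

* Toxicity duration is not modelled with tunnel states; disutilities are
  instantaneous reward decrements.
* Between-arm differences are small relative to totals: they scale with
  carrier prevalence (6.3%) and with the carrier's exposure to standard
  dose (about five months on average before toxicity or progression
  intervenes). Conclusions about cost-effectiveness are therefore highly
  sensitive to the treatment-death inputs and, at these base-case values,
  the ICER lies near the conventional $100,000/QALY threshold rather than
  far below it.
* The Gompertz table approximates female all-cause mortality only; no
  male or cause-deleted tables.
* Genotype test sensitivity/specificity is not modelled (the test is
  treated as perfect), complete DPD deficiency is excluded, and the payer
  perspective omits societal costs.
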