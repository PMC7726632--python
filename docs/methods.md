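# Methods

## Model

`pfcea` implements a decision-analytic cost-effectiveness model for
frontline maintenance therapy in newly diagnosed, advanced epithelial
ovarian cancer after response to platinum-based chemotherapy. Three
cohorts, defined by molecular signature, are modelled separately: *BRCA*
variant carriers; homologous-recombination-deficient (HRD) *BRCA*
wild-type tumors; and homologous-recombination-proficient (HRP) tumors.
Each cohort compares maintenance strategies (olaparib monotherapy in the
*BRCA* cohort only; olaparib-bevacizumab; bevacizumab; niraparib) against
no maintenance over a fixed 24-month horizon with no discounting and no
modelled drug discontinuation. Markov state transitions are deliberately
avoided: the trials underlying the inputs report progression-free survival
(PFS) only, so the model partitions patients between "progression-free"
and "progressed" directly from PFS summaries.

**Effectiveness.** The unit is progression-free life-years saved (PF-LYS):

> PF-LYS = ΔPFS (years, vs no maintenance) × S(24) (probability
> progression-free at 24 months)

Overall survival and quality adjustment are out of scope (no OS data; QoL
instruments differ between the source trials). For workflows that start
from survival curves instead of summary inputs, the package also computes
restricted mean progression-free survival as the area under a
right-continuous Kaplan-Meier step function up to the horizon
(`restricted_mean_pf_years`), and the PFS advantage as the
restricted-mean difference between arms.

**Costs.** Undiscounted 2020 USD from a US healthcare perspective. Each
strategy's 24-month total is

> total = months_on_drug × monthly price + adverse-event cost +
> monitoring/administration residual

with 24 charged monthly cycles for the oral regimens. Detailed unit costs
(labs, office visits, CA-125, infusion administration) are not separately
re-priced: the monitoring/administration component is stored as the
residual that the published totals uniquely determine (olaparib $3 055,
niraparib $3 051, olaparib-bevacizumab $5 352), which reproduces every
published total to the dollar and every published threshold. Adverse-event
costs are a lump sum over the horizon (event probabilities treated as
constant in time, as the trials report summed events).

**Bevacizumab monotherapy** has neither a published cost decomposition nor
published efficacy inputs; it is carried as a total-cost override
($133 591) and a PF-LYS override per cohort (0.26 / 0.18 / 0.23). This
avoids inventing unprinted numbers, at the price that per-component
sensitivity analyses are inapplicable to it (the package raises a named
error rather than silently varying an undefined parameter).

**ICER and classification.** For each comparator, ICER = incremental cost
/ incremental PF-LYS, judged against a willingness-to-pay (WTP) threshold
of $100 000/PF-LYS. A nonpositive effectiveness difference leaves the
ICER undefined (flagged; additionally "dominated" when the strategy also
costs more). No published comparison is cost-effective at the threshold;
the package reproduces that classification.

## One-way deterministic sensitivity analysis

Total cost is affine in each cost parameter and PF-LYS is separable in
each efficacy parameter, so every cost-effectiveness threshold has a
closed form; with m charged cycles, k the incremental non-drug cost, and
referent total R:

| parameter                | threshold                                | not reachable when |
|--------------------------|------------------------------------------|--------------------|
| monthly price P          | P* = (WTP·ΔPF-LYS − m·f − k)/m           | P* < 0             |
| adverse-event cost A     | A* = WTP·ΔPF-LYS − (drug + monitoring − R) | A* < 0           |
| PFS advantage Δ (years)  | Δ* = inc. cost/(WTP·S24)                 | S24 = 0            |
| 24-month probability S24 | S24* = inc. cost/(WTP·Δ)                 | S24* > 1 or Δ = 0  |

(f is the fixed other-component monthly cost when only one drug's share of
a combination price is varied; otherwise 0.) Admissible domains are costs
≥ 0, probability ≤ 1, years unbounded above; a threshold outside its
domain is reported as the distinguished token NR, never clamped or
zeroed. A Brent root-finder over the same model (`bisection_threshold`)
serves as an independent numeric check and as the fallback for non-affine
extensions; closed form and root-finder agree to 1e−6 relative on every
defined fixture threshold, and every defined threshold substituted back
into the model returns ICER = WTP to 1e−6 relative.

One-way ranges evaluate the ICER at (1 ± r) times a parameter's input
value (tornado data), with r = 0.5 for cost parameters and r = 0.1 for
PFS quantities by default, matching the published ranges.

### Known reproduction limits

The published inputs are printed at 2–3 significant figures while the
published outputs were computed from unrounded values. Consequences,
verified arithmetically and deliberately not papered over:

* Published incremental costs are $1 above the difference of the
  published totals (e.g. 418 848 − 3 051 = 415 797, printed 415 798); the
  package differences totals.
* ICERs recomputed from printed inputs agree with the published column to
  0.5% for five of nine comparisons; the bevacizumab rows (overrides are
  printed at 2 d.p.) and the niraparib HRP row (printed effectiveness
  product 0.046 vs implied unrounded ≈0.045) deviate by 1.1–2.2%. The
  corresponding tests assert the 0.5% band and fail honestly.
* All PFS-advantage thresholds reproduce the published 2-decimal values
  exactly; price thresholds agree within 0.5% except the
  olaparib-bevacizumab combined-price cell in the HRP cohort (682.46
  computed vs 686 printed, 0.52%). The published $435 olaparib-component
  price within the combination is not reproducible at all under the
  additive decomposition (which gives 561.21) because the bevacizumab
  share of the combination's monthly cost was never printed; the
  component-price operation exists and the other component cells (NR)
  reproduce.

## Probabilistic sensitivity analysis

`run_psa` microsimulates each base case: every simulated patient draws an
independent parameter set — monthly (or override total) cost ±50%,
adverse-event cost ±50%, PFS advantage ±10%, 24-month probability ±10%
(clipped to [0, 1]) — and is pushed through the deterministic engine to a
patient-level ICER against the fixed referent. Trials are batches of
patients (default 1000 trials × 1000 patients); the headline statistic is
the fraction of patients with a defined ICER ≤ WTP, and `ceac` tabulates
that fraction over a WTP grid (nondecreasing per strategy by
construction).

Design choices where the published description is open:

* **Distribution family.** Only ± ranges are published, not a family.
  Uniform over the stated interval is the default (least informative
  consistent with the ranges); triangular with the input value as mode is
  available. The published "10/1000 patients (1%)" for olaparib in the
  *BRCA* cohort is therefore treated as a qualitative anchor (small,
  nonzero, best among strategies) rather than an exact target; the
  uniform-family run at these ranges gives a fraction of the same order
  (a few percent).
* **Independence.** Parameters are sampled independently; no correlation
  structure is published.
* **Degenerate contract.** Zero-width ranges collapse every sample to the
  deterministic inputs exactly (no residual patient-level noise), so the
  degenerate PSA equals the deterministic model — this is the verifiable
  contract of the microsimulation design, and is tested as an exact
  equality.
* **Random stream.** One `numpy` SeedSequence per run, one spawned child
  stream per strategy in comparator order, all trials and patients drawn
  vectorized from that stream; identical seed and configuration give
  bit-identical results.

Monte-Carlo error of the cost-effective fraction shrinks as n^(−1/2);
this is checked empirically at two sample sizes in the suite.

## Synthetic trial generator

`pfcea.synthetic` emulates the shape of the unavailable trial-level
inputs so the whole pipeline is testable without any download:
exponential progression times (control hazard ln 2 / control median;
treatment hazard = HR × control hazard), independent exponential dropout
censoring plus administrative censoring at the horizon, Kaplan-Meier
estimation via `lifelines`, and conversion to a `BaseCase` (24-month
probability from the treatment curve, advantage from the restricted-mean
difference, costs from a jittered cost specification).
`spec_for_target_advantage` solves the hazard ratio that yields a
requested restricted-mean gain and refuses infeasible targets: the gain
over a horizon H is bounded by H minus the control restricted mean, so
e.g. a 3-year advantage is not representable over a 24-month horizon.
Defaults (cohort 1000 per arm, control median 14 months, HR 0.5,
censoring 0.01/month) are in the range typical of frontline maintenance
trials in this disease.

The generator is a stand-in with known limitations: real PFS curves are
not exponential (plateaus, delayed separation), censoring is not purely
random, and cohort inputs in the published model come from subgroup
analyses with their own sampling error. Passing recovery tests therefore
show the estimators are correct under the stated model, not that the
published trial curves are reproduced.

## Problem sizes and numerical choices

The deterministic analyses are closed-form desk computations (< 1 s). The
study-scale PSA (1000 × 1000 per cohort) runs in ~1 s vectorized; unit
tests use smaller designs (≤ 50 × 100), and the synthetic recovery tests
use cohorts of 400–10 000. Currency is held as floats (inputs are exact
dollar amounts; no rounding is applied internally — display formatting
rounds PF-LYS to 2 d.p. and dollars to the unit). Ties and degenerate
inputs: zero-width one-way ranges are admissible and collapse to the base
ICER; an empty comparator list is a valid base case yielding empty result
sets; NR cells render as "NR" in every output, never 0 or blank.
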