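# pfcea

Cost-effectiveness analysis of frontline **maintenance therapy in
advanced epithelial ovarian cancer**, measured in US dollars per
**progression-free life-year saved (PF-LYS)**.

After response to first-line platinum chemotherapy, patients may receive
maintenance therapy — a PARP inhibitor (olaparib, niraparib),
bevacizumab, or olaparib-bevacizumab — to delay progression. These drugs
carry large price tags, and the pivotal trials report progression-free
survival (PFS) only. `pfcea` implements the decision-analytic model that
makes the value question tractable under those constraints, for health
economists and oncology researchers:

* **Effectiveness:** PF-LYS = ΔPFS (years, vs no maintenance) ×
  S(24 months), the probability of being progression-free at 24 months —
  or, from Kaplan-Meier curves, the restricted-mean PFS difference.
* **Costs:** 24-month totals from monthly acquisition price, lump
  adverse-event cost, and a monitoring/administration residual
  (undiscounted 2020 USD).
* **ICER:** incremental cost / incremental PF-LYS versus no maintenance,
  judged at a willingness-to-pay (WTP) threshold of $100 000/PF-LYS,
  stratified by molecular signature (*BRCA* variant; HR-deficient *BRCA*
  wild type; HR-proficient).
* **One-way sensitivity analysis:** closed-form cost-effective
  thresholds for drug price, adverse-event cost, PFS advantage and
  24-month PFS probability, with not-reachable (NR) semantics and tornado
  ranges; a bisection root-finder cross-checks every closed form.
* **Probabilistic sensitivity analysis:** seeded microsimulation (default
  1000 trials × 1000 patients; costs ±50%, PFS quantities ±10%) with
  cost-effectiveness acceptability curves.
* **Synthetic data:** an exponential proportional-hazards trial
  generator (Kaplan-Meier estimation via `lifelines`) so every stage is
  testable without external data.

## Worked example

```python
from pfcea import (Cohort, reference_base_cases, evaluate_base_case,
                   solve_price_threshold)

brca = {c.cohort: c for c in reference_base_cases()}[Cohort.BRCA_VARIANT]
for r in evaluate_base_case(brca):
    print(f"{r.strategy_name:<22s} dPF-LYS {r.incremental_pf_lys:.2f}  "
          f"ICER ${r.icer:,.0f}/PF-LYS  CE: {r.cost_effective}")

olaparib = brca.strategy("olaparib")
t = solve_price_threshold(olaparib, brca.referent, brca.wtp)
print(f"olaparib becomes cost-effective at ${t.threshold_value:,.2f}/month")
```

prints

```
olaparib               dPF-LYS 2.23  ICER $186,674/PF-LYS  CE: False
olaparib_bevacizumab   dPF-LYS 1.48  ICER $366,199/PF-LYS  CE: False
bevacizumab            dPF-LYS 0.26  ICER $502,077/PF-LYS  CE: False
niraparib              dPF-LYS 0.46  ICER $1,073,458/PF-LYS  CE: False
olaparib becomes cost-effective at $8,954.96/month
```

No maintenance strategy is cost-effective at $100 000/PF-LYS in any
cohort; olaparib monotherapy for *BRCA* carriers comes closest and would
clear the threshold if its $16 999 monthly price fell by about 47% to
roughly $8 955. The same analyses run from the shell:

```bash
pfcea run --reference-fixtures --out results/
pfcea run --reference-fixtures --psa --trials 1000 --patients 1000 --seed 7 --out results/
pfcea run --config my_model.yaml --wtp 150000 --out results/
```

writing per-cohort CSVs (base-case table, threshold table with NR cells,
tornado data, PSA samples and CEAC) plus a plain-text summary and run
log. `src/pfcea/data/reference.yaml` documents the configuration schema;
`pfcea.save_config` writes the same format for synthetic or custom base
cases.

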