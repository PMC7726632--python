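horizon_months: 24.0
wtp: 100000.0
base_cases:
- cohort: brca_variant
  referent:
    name: no_maintenance
    monitoring_cost: 3051.0
  comparators:
  - name: olaparib
    monthly_drug_cost: 16999.0
    months_on_drug: 24.0
    ae_cost: 7817.0
    monitoring_cost: 3055.0
    pfs_advantage_years: 3.01
    pfs24_probability: 0.74
  - name: olaparib_bevacizumab
    monthly_drug_cost: 22249.0
    months_on_drug: 24.0
    ae_cost: 6430.0
    monitoring_cost: 5352.0
    pfs_advantage_years: 1.95
    pfs24_probability: 0.76
  - name: bevacizumab
    total_cost_override: 133591.0
    pf_lys_override: 0.26
  - name: niraparib
    monthly_drug_cost: 19947.0
    months_on_drug: 24.0
    ae_cost: 10447.0
    monitoring_cost: 3051.0
    pfs_advantage_years: 0.93
    pfs24_probability: 0.49
- cohort: hrd_brca_wt
  referent:
    name: no_maintenance
    monitoring_cost: 3051.0
  comparators:
  - name: olaparib_bevacizumab
    monthly_drug_cost: 22249.0
    months_on_drug: 24.0
    ae_cost: 6430.0
    monitoring_cost: 5352.0
    pfs_advantage_years: 1.66
    pfs24_probability: 0.52
  - name: bevacizumab
    total_cost_override: 133591.0
    pf_lys_override: 0.18
  - name: niraparib
    monthly_drug_cost: 19947.0
    months_on_drug: 24.0
    ae_cost: 10447.0
    monitoring_cost: 3051.0
    pfs_advantage_years: 0.95
    pfs24_probability: 0.48
- cohort: hr_proficient
  referent:
    name: no_maintenance
    monitoring_cost: 3051.0
  comparators:
  - name: olaparib_bevacizumab
    monthly_drug_cost: 22249.0
    months_on_drug: 24.0
    ae_cost: 6430.0
    monitoring_cost: 5352.0
    pfs_advantage_years: 0.93
    pfs24_probability: 0.27
  - name: bevacizumab
    total_cost_override: 133591.0
    pf_lys_override: 0.23
  - name: niraparib
    monthly_drug_cost: 19947.0
    months_on_drug: 24.0
    ae_cost: 10447.0
    monitoring_cost: 3051.0
    pfs_advantage_years: 0.23
    pfs24_probability: 0.2
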