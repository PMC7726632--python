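"""Publication-style reporting: base-case tables, threshold tables,
tornado data and PSA summaries.

Builders call the engines once and hand result objects to formatters; the
formatters only format (no quantity is recomputed at the reporting layer).
Not-reachable thresholds and undefined ICERs render as the token ``NR`` —
never as 0 or an empty cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dsa
from .costs import total_cost
from .engine import CEAResult, evaluate_base_case
from .errors import ParameterNotApplicableError
from .inputs import BaseCase
from .psa import PSAConfig, PSAResult, ceac, run_psa

NR_TOKEN = "NR"

_THRESHOLD_SOLVERS = (
    ("price", dsa.solve_price_threshold),
    ("ae_cost", dsa.solve_ae_cost_threshold),
    ("pfs_advantage", dsa.solve_pfs_advantage_threshold),
    ("pfs24_probability", dsa.solve_pfs_probability_threshold),
)

_TORNADO_PARAMETERS = {
    dsa.ThresholdParameter.COMBINED_MONTHLY_COST: "cost_relative_range",
    dsa.ThresholdParameter.AE_COST: "cost_relative_range",
    dsa.ThresholdParameter.PFS_ADVANTAGE: "pfs_relative_range",
    dsa.ThresholdParameter.PFS24_PROBABILITY: "pfs_relative_range",
}


@dataclass(frozen=True)
class ReportBundle:
    """Everything one analysis run reports for a single base case."""

    base_case: BaseCase
    cea_results: list[CEAResult]
    base_case_table: pd.DataFrame
    threshold_table: pd.DataFrame
    tornado_table: pd.DataFrame
    psa_result: PSAResult | None = None
    psa_summary: pd.DataFrame | None = None
    ceac_table: pd.DataFrame | None = None


def base_case_frame(base_case: BaseCase,
                    results: list[CEAResult] | None = None) -> pd.DataFrame:
    """Summary rows per strategy: 24-month cost, incremental cost,
    incremental PF-LYS, ICER (unrounded; NaN where undefined)."""
    if results is None:
        results = evaluate_base_case(base_case)
    rows = [{
        "strategy": base_case.referent.name,
        "cost_24m": total_cost(base_case.referent).total,
        "incremental_cost": 0.0,
        "incremental_pf_lys": 0.0,
        "icer": np.nan,
        "cost_effective": np.nan,
    }]
    for strategy, r in zip(base_case.comparators, results):
        rows.append({
            "strategy": strategy.name,
            "cost_24m": total_cost(strategy).total,
            "incremental_cost": r.incremental_cost,
            "incremental_pf_lys": r.incremental_pf_lys,
            "icer": r.icer if r.icer is not None else np.nan,
            "cost_effective": r.cost_effective,
        })
    return pd.DataFrame(rows)


def threshold_frame(base_case: BaseCase) -> pd.DataFrame:
    """One-way cost-effective threshold values for every applicable
    (strategy, parameter) pair; inapplicable pairs are omitted."""
    rows = []
    for strategy in base_case.comparators:
        for label, solver in _THRESHOLD_SOLVERS:
            try:
                result = solver(strategy, base_case.referent, base_case.wtp)
            except ParameterNotApplicableError:
                continue
            rows.append({
                "strategy": strategy.name,
                "parameter": label,
                "input_value": result.input_value,
                "threshold_value": (result.threshold_value
                                    if not result.not_reachable else np.nan),
                "not_reachable": result.not_reachable,
            })
    return pd.DataFrame(rows)


def tornado_frame(base_case: BaseCase, cost_relative_range: float = 0.5,
                  pfs_relative_range: float = 0.1) -> pd.DataFrame:
    """Low/high ICERs per (strategy, parameter) for tornado plotting."""
    ranges = {"cost_relative_range": cost_relative_range,
              "pfs_relative_range": pfs_relative_range}
    rows = []
    for strategy in base_case.comparators:
        for parameter, range_key in _TORNADO_PARAMETERS.items():
            try:
                r = dsa.one_way_range(strategy, base_case.referent, parameter,
                                      ranges[range_key], base_case.wtp)
            except ParameterNotApplicableError:
                continue
            rows.append({
                "strategy": strategy.name,
                "parameter": parameter.value,
                "low_value": r.low_value,
                "high_value": r.high_value,
                "low_icer": np.nan if r.low_icer is None else r.low_icer,
                "high_icer": np.nan if r.high_icer is None else r.high_icer,
                "base_icer": np.nan if r.base_icer is None else r.base_icer,
            })
    return pd.DataFrame(rows)


def psa_summary_frame(result: PSAResult) -> pd.DataFrame:
    """Per-strategy PSA summary: mean/median sampled ICER and the fraction
    of patients cost-effective at the WTP threshold."""
    rows = []
    for name, samples in result.icer_samples.items():
        flat = samples.ravel()
        rows.append({
            "strategy": name,
            "mean_icer": float(np.nanmean(flat)),
            "median_icer": float(np.nanmedian(flat)),
            "fraction_ce_at_wtp": result.fraction_ce_at_wtp[name],
        })
    return pd.DataFrame(rows)


def build_report(base_case: BaseCase, psa_config: PSAConfig | None = None,
                 cost_relative_range: float = 0.5,
                 pfs_relative_range: float = 0.1,
                 wtp_grid: np.ndarray | None = None) -> ReportBundle:
    """Run the full deterministic analysis (and optionally the PSA) for one
    base case and bundle the resulting tables."""
    results = evaluate_base_case(base_case)
    psa_result = psa_summary = ceac_table = None
    if psa_config is not None:
        psa_result = run_psa(base_case, psa_config)
        psa_summary = psa_summary_frame(psa_result)
        if wtp_grid is None:
            wtp_grid = np.linspace(0, 2_000_000, 41)
        ceac_table = ceac(psa_result, wtp_grid)
    return ReportBundle(
        base_case=base_case,
        cea_results=results,
        base_case_table=base_case_frame(base_case, results),
        threshold_table=threshold_frame(base_case),
        tornado_table=tornado_frame(base_case, cost_relative_range, pfs_relative_range),
        psa_result=psa_result,
        psa_summary=psa_summary,
        ceac_table=ceac_table,
    )


# ---------------------------------------------------------------------------
# Display formatting
# ---------------------------------------------------------------------------
def format_dollars(value: float) -> str:
    """Whole dollars with space-grouped thousands; NR for undefined."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return NR_TOKEN
    return f"{value:,.0f}".replace(",", " ")


def format_years(value: float) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return NR_TOKEN
    return f"{value:.2f}"


def render_summary(bundle: ReportBundle) -> str:
    """Human-readable run summary (idempotent: pure function of the bundle)."""
    bc = bundle.base_case
    lines = [
        f"Base case: {bc.cohort.label}",
        f"Horizon: {bc.horizon_months:g} months; "
        f"WTP: ${format_dollars(bc.wtp)}/PF-LYS",
        "",
        "Strategy summary (vs no maintenance):",
    ]
    for i, (_, row) in enumerate(bundle.base_case_table.iterrows()):
        icer_text = ("[referent]" if i == 0
                     else f"ICER ${format_dollars(row['icer'])}/PF-LYS")
        lines.append(
            f"  {row['strategy']:<22s} cost ${format_dollars(row['cost_24m']):>9s}  "
            f"dPF-LYS {format_years(row['incremental_pf_lys']):>6s}  {icer_text}"
        )
    lines.append("")
    lines.append("Cost-effective threshold values (NR = not reachable):")
    for _, row in bundle.threshold_table.iterrows():
        value = NR_TOKEN if row["not_reachable"] else f"{row['threshold_value']:.2f}"
        lines.append(
            f"  {row['strategy']:<22s} {row['parameter']:<18s} "
            f"input {row['input_value']:>10.2f}  threshold {value}"
        )
    if bundle.psa_summary is not None:
        lines.append("")
        lines.append("Probabilistic sensitivity analysis:")
        for _, row in bundle.psa_summary.iterrows():
            lines.append(
                f"  {row['strategy']:<22s} mean ICER "
                f"${format_dollars(row['mean_icer'])}/PF-LYS  "
                f"P(CE at WTP) = {row['fraction_ce_at_wtp']:.4f}"
            )
    return "\n".join(lines) + "\n"
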