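"""Per-strategy cost aggregation over the model horizon.

Total cost is additive — drug acquisition (monthly price times charged
cycles) plus lump adverse-event cost plus the monitoring/administration
residual — unless the strategy carries a published total-cost override,
which wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .inputs import StrategyInputs


@dataclass(frozen=True)
class CostBreakdown:
    """Cost components (USD over the horizon) for one strategy."""

    strategy_name: str
    drug_acquisition: float
    ae_cost: float
    monitoring_cost: float
    total: float
    override_applied: bool = False


def total_cost(strategy: StrategyInputs) -> CostBreakdown:
    """Aggregate a strategy's 24-month cost from its components.

    With a ``total_cost_override`` the total equals the override and the
    breakdown flags it; otherwise
    ``total = months_on_drug x monthly_drug_cost + ae_cost + monitoring_cost``.
    """
    drug = strategy.months_on_drug * strategy.monthly_drug_cost
    if strategy.total_cost_override is not None:
        return CostBreakdown(
            strategy_name=strategy.name,
            drug_acquisition=drug,
            ae_cost=strategy.ae_cost,
            monitoring_cost=strategy.monitoring_cost,
            total=strategy.total_cost_override,
            override_applied=True,
        )
    return CostBreakdown(
        strategy_name=strategy.name,
        drug_acquisition=drug,
        ae_cost=strategy.ae_cost,
        monitoring_cost=strategy.monitoring_cost,
        total=drug + strategy.ae_cost + strategy.monitoring_cost,
    )


def incremental_cost(strategy: StrategyInputs, referent: StrategyInputs) -> float:
    """Difference in total horizon cost versus the referent (may be negative)."""
    return total_cost(strategy).total - total_cost(referent).total


def cost_frame(strategies: Iterable[StrategyInputs]) -> pd.DataFrame:
    """One row per strategy with its cost breakdown (CSV-ready)."""
    rows = []
    for s in strategies:
        b = total_cost(s)
        rows.append(
            {
                "strategy": b.strategy_name,
                "drug_acquisition": b.drug_acquisition,
                "ae_cost": b.ae_cost,
                "monitoring_cost": b.monitoring_cost,
                "total": b.total,
                "override_applied": b.override_applied,
            }
        )
    return pd.DataFrame(rows)
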