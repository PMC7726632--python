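"""Effectiveness and incremental cost-effectiveness computations.

Effectiveness is measured in progression-free life-years saved (PF-LYS):
the gain in progression-free survival (years) versus no maintenance,
multiplied by the probability of remaining progression-free at 24 months.
This is the partitioned-survival shortcut used when trials report only
progression-free outcomes; the restricted-mean path over a Kaplan-Meier
step curve is provided for workflows that start from survival curves
rather than published summary inputs.

The ICER for a strategy versus the referent is incremental cost divided by
incremental PF-LYS; it is undefined (flagged, not an error) when the
effectiveness difference is nonpositive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import incremental_cost
from .errors import ExtrapolationError, InputValidationError
from .inputs import BaseCase, StrategyInputs


def pf_lys(strategy: StrategyInputs) -> float:
    """Progression-free life-years saved versus the referent.

    Uses ``pf_lys_override`` when present, otherwise
    ``pfs_advantage_years x pfs24_probability``.
    """
    if strategy.pf_lys_override is not None:
        return strategy.pf_lys_override
    return strategy.pfs_advantage_years * strategy.pfs24_probability


def incremental_pf_lys(strategy: StrategyInputs, referent: StrategyInputs) -> float:
    return pf_lys(strategy) - pf_lys(referent)


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of one strategy against the referent."""

    strategy_name: str
    incremental_cost: float
    incremental_pf_lys: float
    icer: float | None  #: USD per PF-LYS; None when incremental PF-LYS <= 0
    cost_effective: bool  #: ICER defined and <= the willingness-to-pay threshold
    dominated: bool  #: costs more while gaining no progression-free time


def icer(strategy: StrategyInputs, referent: StrategyInputs,
         wtp: float) -> CEAResult:
    """Incremental cost-effectiveness ratio versus the referent.

    A nonpositive effectiveness difference leaves the ICER undefined; if the
    strategy additionally costs more it is dominated. A strategy that costs
    no more and gains progression-free time has ICER <= 0 and is
    cost-effective at any positive willingness-to-pay.
    """
    d_cost = incremental_cost(strategy, referent)
    d_eff = incremental_pf_lys(strategy, referent)
    if d_eff > 0:
        ratio = d_cost / d_eff
        return CEAResult(
            strategy_name=strategy.name,
            incremental_cost=d_cost,
            incremental_pf_lys=d_eff,
            icer=ratio,
            cost_effective=ratio <= wtp,
            dominated=False,
        )
    return CEAResult(
        strategy_name=strategy.name,
        incremental_cost=d_cost,
        incremental_pf_lys=d_eff,
        icer=None,
        cost_effective=False,
        dominated=d_cost > 0,
    )


def evaluate_base_case(base_case: BaseCase) -> list[CEAResult]:
    """ICER of every comparator versus the base case's referent."""
    return [icer(s, base_case.referent, base_case.wtp) for s in base_case.comparators]


# ---------------------------------------------------------------------------
# Survival-curve utilities
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step function of progression-free probability.

    ``times`` are nondecreasing months starting at 0; ``probabilities`` are
    nonincreasing values in [0, 1] starting at 1. Between knots the curve
    holds the value at the preceding knot.
    """

    times: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", p)
        if t.ndim != 1 or p.ndim != 1 or t.shape != p.shape or t.size == 0:
            raise InputValidationError("times and probabilities must be matching 1-d arrays")
        if t[0] != 0 or p[0] != 1:
            raise InputValidationError("curve must start at (t=0, p=1)")
        if np.any(np.diff(t) < 0):
            raise InputValidationError("times must be nondecreasing")
        if np.any(np.diff(p) > 0):
            raise InputValidationError("probabilities must be nonincreasing")
        if p[-1] < 0 or p[0] > 1:
            raise InputValidationError("probabilities must lie in [0, 1]")

    def probability_at(self, t: float) -> float:
        """Curve value at time ``t`` months (right-continuous lookup)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.probabilities[idx])


def restricted_mean_pf_years(curve: SurvivalCurve, horizon_months: float) -> float:
    """Restricted mean progression-free survival: step-function AUC on
    [0, horizon], converted from months to years.

    Raises :class:`ExtrapolationError` if the curve's follow-up ends before
    the horizon (the step function is only known up to its last knot).
    """
    if horizon_months <= 0:
        raise InputValidationError("horizon_months must be positive")
    if curve.times[-1] < horizon_months:
        raise ExtrapolationError(
            f"curve follow-up ends at {curve.times[-1]:g} months, before the "
            f"{horizon_months:g}-month horizon"
        )
    t = np.clip(curve.times, None, horizon_months)
    # area of each constant piece [t_i, t_{i+1}) at height p_i, plus the tail
    # from the last knot below the horizon out to the horizon
    widths = np.diff(np.append(t, horizon_months))
    widths = np.clip(widths, 0.0, None)
    auc_months = float(np.sum(widths * curve.probabilities))
    return auc_months / 12.0
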