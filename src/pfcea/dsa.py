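"""One-way deterministic sensitivity analysis.

Two flavours are provided for every varied parameter:

* **Threshold solving** — the parameter value at which the strategy's ICER
  versus the referent equals the willingness-to-pay threshold. Because the
  total cost is affine in each cost parameter and the effectiveness formula
  is separable in each efficacy parameter, every threshold has a closed
  form. A threshold outside the parameter's admissible domain (prices and
  adverse-event costs cannot fall below $0; a probability cannot exceed 1)
  is reported as not reachable (NR) rather than clamped.

* **Range evaluation** — the ICERs at the ends of a relative interval
  around the input value (cost parameters +/-50%, progression-free survival
  quantities +/-10% in the published analysis), the inputs of a tornado
  diagram.

A bisection root-finder over the same model is included as an independent
numeric check on the closed forms.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .costs import incremental_cost, total_cost
from .engine import icer, incremental_pf_lys
from .errors import InputValidationError, ParameterNotApplicableError
from .inputs import StrategyInputs


class ThresholdParameter(enum.Enum):
    MONTHLY_DRUG_COST = "monthly_drug_cost"
    COMBINED_MONTHLY_COST = "combined_monthly_cost"
    AE_COST = "ae_cost"
    PFS_ADVANTAGE = "pfs_advantage"
    PFS24_PROBABILITY = "pfs24_probability"


@dataclass(frozen=True)
class ThresholdResult:
    """Cost-effective threshold for one varied parameter, or NR."""

    strategy_name: str
    parameter: ThresholdParameter
    input_value: float
    threshold_value: float | None  #: None when not reachable
    admissible_domain: tuple[float, float]

    @property
    def not_reachable(self) -> bool:
        return self.threshold_value is None


@dataclass(frozen=True)
class OneWayRange:
    """ICERs at the ends of a one-way parameter interval (tornado bar)."""

    strategy_name: str
    parameter: ThresholdParameter
    low_value: float
    high_value: float
    low_icer: float | None   #: ICER with the parameter at low_value
    high_icer: float | None
    base_icer: float | None

    @property
    def width(self) -> float:
        if self.low_icer is None or self.high_icer is None:
            return math.nan
        return abs(self.high_icer - self.low_icer)


def _require_decomposition(strategy: StrategyInputs, parameter: str) -> None:
    if not strategy.has_cost_decomposition:
        raise ParameterNotApplicableError(
            f"strategy {strategy.name} carries a total-cost override; "
            f"{parameter} is not a free parameter"
        )


def _nondrug_increment(strategy: StrategyInputs, referent: StrategyInputs) -> float:
    """Incremental non-drug cost: AE + monitoring minus the referent total."""
    return strategy.ae_cost + strategy.monitoring_cost - total_cost(referent).total


def solve_price_threshold(strategy: StrategyInputs, referent: StrategyInputs,
                          wtp: float, component_cost: float | None = None,
                          parameter: ThresholdParameter | None = None) -> ThresholdResult:
    """Monthly price at which the strategy becomes cost-effective.

    By default the whole monthly acquisition price (for a combination
    regimen, the combined monthly cost) is varied. Passing
    ``component_cost`` varies only that share of the monthly price, holding
    the remainder (the other drug in a combination) fixed.

    Closed form: with ``m`` charged cycles, fixed other-component monthly
    cost ``f`` and non-drug incremental cost ``k``,
    ``P* = (wtp x dPF-LYS - m x f - k) / m``; not reachable when ``P* < 0``
    (a price cannot fall below zero).
    """
    _require_decomposition(strategy, "monthly drug cost")
    m = strategy.months_on_drug
    if m <= 0:
        raise ParameterNotApplicableError(
            f"strategy {strategy.name} charges no monthly cycles"
        )
    if component_cost is None:
        fixed_other = 0.0
        input_value = strategy.monthly_drug_cost
        if parameter is None:
            parameter = ThresholdParameter.COMBINED_MONTHLY_COST
    else:
        if not 0 <= component_cost <= strategy.monthly_drug_cost:
            raise InputValidationError(
                "component_cost must lie within [0, monthly_drug_cost]"
            )
        fixed_other = strategy.monthly_drug_cost - component_cost
        input_value = component_cost
        if parameter is None:
            parameter = ThresholdParameter.MONTHLY_DRUG_COST
    d_eff = incremental_pf_lys(strategy, referent)
    p_star = (wtp * d_eff - m * fixed_other - _nondrug_increment(strategy, referent)) / m
    return ThresholdResult(
        strategy_name=strategy.name,
        parameter=parameter,
        input_value=input_value,
        threshold_value=p_star if p_star >= 0 else None,
        admissible_domain=(0.0, math.inf),
    )


def solve_ae_cost_threshold(strategy: StrategyInputs, referent: StrategyInputs,
                            wtp: float) -> ThresholdResult:
    """Adverse-event cost at which the strategy becomes cost-effective.

    ``A* = wtp x dPF-LYS - (drug acquisition + monitoring - referent
    total)``; not reachable when even a zero adverse-event cost leaves the
    ICER above the threshold (``A* < 0``).
    """
    _require_decomposition(strategy, "adverse-event cost")
    d_eff = incremental_pf_lys(strategy, referent)
    drug = strategy.months_on_drug * strategy.monthly_drug_cost
    a_star = (wtp * d_eff
              - (drug + strategy.monitoring_cost - total_cost(referent).total))
    return ThresholdResult(
        strategy_name=strategy.name,
        parameter=ThresholdParameter.AE_COST,
        input_value=strategy.ae_cost,
        threshold_value=a_star if a_star >= 0 else None,
        admissible_domain=(0.0, math.inf),
    )


def solve_pfs_advantage_threshold(strategy: StrategyInputs, referent: StrategyInputs,
                                  wtp: float) -> ThresholdResult:
    """Progression-free survival advantage (years) required for
    cost-effectiveness at fixed costs and 24-month probability.

    ``D* = incremental cost / (wtp x pfs24_probability)``; years are
    unbounded above, so the threshold is always reachable unless the
    24-month probability is zero (or effectiveness is fixed by an
    override).
    """
    domain = (0.0, math.inf)
    if strategy.pf_lys_override is not None or strategy.pfs24_probability <= 0:
        return ThresholdResult(strategy.name, ThresholdParameter.PFS_ADVANTAGE,
                               strategy.pfs_advantage_years, None, domain)
    d_cost = incremental_cost(strategy, referent)
    d_star = max(0.0, d_cost / (wtp * strategy.pfs24_probability))
    return ThresholdResult(strategy.name, ThresholdParameter.PFS_ADVANTAGE,
                           strategy.pfs_advantage_years, d_star, domain)


def solve_pfs_probability_threshold(strategy: StrategyInputs, referent: StrategyInputs,
                                    wtp: float) -> ThresholdResult:
    """24-month progression-free probability required for cost-effectiveness.

    ``p* = incremental cost / (wtp x pfs_advantage_years)``; not reachable
    when ``p* > 1`` (a probability cannot exceed 1) or when the advantage is
    zero or fixed by an override.
    """
    domain = (0.0, 1.0)
    if strategy.pf_lys_override is not None or strategy.pfs_advantage_years <= 0:
        return ThresholdResult(strategy.name, ThresholdParameter.PFS24_PROBABILITY,
                               strategy.pfs24_probability, None, domain)
    d_cost = incremental_cost(strategy, referent)
    p_star = max(0.0, d_cost / (wtp * strategy.pfs_advantage_years))
    return ThresholdResult(strategy.name, ThresholdParameter.PFS24_PROBABILITY,
                           strategy.pfs24_probability,
                           p_star if p_star <= 1.0 else None, domain)


# ---------------------------------------------------------------------------
# Parameter substitution, range evaluation, and the bisection cross-check
# ---------------------------------------------------------------------------
def with_parameter(strategy: StrategyInputs, parameter: ThresholdParameter,
                   value: float, component_cost: float | None = None) -> StrategyInputs:
    """A copy of the strategy with one sensitivity parameter replaced.

    For ``MONTHLY_DRUG_COST`` with ``component_cost`` given, ``value``
    replaces only that component's share of the monthly price.
    """
    if parameter in (ThresholdParameter.MONTHLY_DRUG_COST,
                     ThresholdParameter.COMBINED_MONTHLY_COST):
        _require_decomposition(strategy, parameter.value)
        if component_cost is not None:
            value = strategy.monthly_drug_cost - component_cost + value
        return dataclasses.replace(strategy, monthly_drug_cost=value)
    if parameter is ThresholdParameter.AE_COST:
        _require_decomposition(strategy, parameter.value)
        return dataclasses.replace(strategy, ae_cost=value)
    if parameter is ThresholdParameter.PFS_ADVANTAGE:
        return dataclasses.replace(strategy, pfs_advantage_years=value)
    if parameter is ThresholdParameter.PFS24_PROBABILITY:
        return dataclasses.replace(strategy, pfs24_probability=value)
    raise ParameterNotApplicableError(str(parameter))


def icer_at(strategy: StrategyInputs, referent: StrategyInputs, wtp: float,
            parameter: ThresholdParameter, value: float,
            component_cost: float | None = None) -> float | None:
    """ICER with one parameter substituted (None when undefined)."""
    modified = with_parameter(strategy, parameter, value, component_cost)
    return icer(modified, referent, wtp).icer


def _base_value(strategy: StrategyInputs, parameter: ThresholdParameter,
                component_cost: float | None) -> float:
    if parameter in (ThresholdParameter.MONTHLY_DRUG_COST,
                     ThresholdParameter.COMBINED_MONTHLY_COST):
        _require_decomposition(strategy, parameter.value)
        return component_cost if component_cost is not None else strategy.monthly_drug_cost
    if parameter is ThresholdParameter.AE_COST:
        _require_decomposition(strategy, parameter.value)
        return strategy.ae_cost
    if parameter is ThresholdParameter.PFS_ADVANTAGE:
        if strategy.pf_lys_override is not None:
            raise ParameterNotApplicableError(
                f"strategy {strategy.name} carries a PF-LYS override"
            )
        return strategy.pfs_advantage_years
    if parameter is ThresholdParameter.PFS24_PROBABILITY:
        if strategy.pf_lys_override is not None:
            raise ParameterNotApplicableError(
                f"strategy {strategy.name} carries a PF-LYS override"
            )
        return strategy.pfs24_probability
    raise ParameterNotApplicableError(str(parameter))


def one_way_range(strategy: StrategyInputs, referent: StrategyInputs,
                  parameter: ThresholdParameter, relative_range: float,
                  wtp: float, component_cost: float | None = None) -> OneWayRange:
    """ICERs with one parameter moved to ``(1 +/- relative_range)`` times its
    input value, all else fixed (one bar of a tornado diagram)."""
    if relative_range < 0:
        raise InputValidationError("relative_range must be nonnegative")
    base = _base_value(strategy, parameter, component_cost)
    low = base * (1 - relative_range)
    high = base * (1 + relative_range)
    if parameter is ThresholdParameter.PFS24_PROBABILITY:
        high = min(high, 1.0)
    return OneWayRange(
        strategy_name=strategy.name,
        parameter=parameter,
        low_value=low,
        high_value=high,
        low_icer=icer_at(strategy, referent, wtp, parameter, low, component_cost),
        high_icer=icer_at(strategy, referent, wtp, parameter, high, component_cost),
        base_icer=icer(strategy, referent, wtp).icer,
    )


def bisection_threshold(strategy: StrategyInputs, referent: StrategyInputs,
                        wtp: float, parameter: ThresholdParameter,
                        component_cost: float | None = None,
                        search_upper: float = 1e9,
                        xtol: float = 1e-9) -> ThresholdResult:
    """Numeric threshold solve by root-finding on ICER(value) - wtp.

    Independent of the closed forms: brackets the root inside the
    parameter's admissible domain and runs Brent's method. Agrees with the
    closed-form solvers to numerical tolerance on every affine/separable
    parameter; kept as the fallback for non-affine model extensions.
    """
    lo, hi = 0.0, search_upper
    if parameter is ThresholdParameter.PFS24_PROBABILITY:
        hi = 1.0
    if parameter in (ThresholdParameter.PFS_ADVANTAGE,
                     ThresholdParameter.PFS24_PROBABILITY):
        if strategy.pf_lys_override is not None:
            return ThresholdResult(strategy.name, parameter,
                                   _base_value_or_nan(strategy, parameter), None,
                                   (lo, hi))

    def objective(value: float) -> float:
        result = icer_at(strategy, referent, wtp, parameter, value, component_cost)
        if result is None:
            # undefined ICER (nonpositive effectiveness): worse than any WTP
            return 1e30
        return result - wtp

    f_lo, f_hi = objective(lo), objective(hi)
    input_value = _base_value(strategy, parameter, component_cost)
    domain = (lo, hi if parameter is ThresholdParameter.PFS24_PROBABILITY else math.inf)
    if f_lo * f_hi > 0:
        # no sign change inside the admissible domain: not reachable
        return ThresholdResult(strategy.name, parameter, input_value, None, domain)
    root = brentq(objective, lo, hi, xtol=xtol, rtol=8.9e-16)
    return ThresholdResult(strategy.name, parameter, input_value, float(root), domain)


def _base_value_or_nan(strategy: StrategyInputs, parameter: ThresholdParameter) -> float:
    try:
        return _base_value(strategy, parameter, None)
    except ParameterNotApplicableError:
        return math.nan
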