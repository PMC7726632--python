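"""Synthetic trial data with the statistical structure the model assumes.

The published analysis starts from Kaplan-Meier progression-free survival
curves and summary efficacy inputs. This module generates that shape of
data from first principles so every downstream stage can be exercised
without any external dataset: exponential progression times under
proportional hazards (control hazard set by the control median; treatment
hazard = hazard ratio x control hazard), independent exponential dropout
censoring plus administrative censoring at the horizon, product-limit
estimation of the two curves, and conversion into a ready-to-analyse
:class:`~pfcea.inputs.BaseCase` (24-month probability from the treatment
curve, progression-free advantage from the restricted-mean difference,
costs from a jittered cost specification).

The exponential model is a deliberately simple stand-in for trial cohorts
with a complete or partial response to chemotherapy; it makes every
generated quantity checkable against closed forms. It is not a claim about
the shape of any real trial's curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import brentq

from .engine import SurvivalCurve, restricted_mean_pf_years
from .errors import InfeasibleAdvantageError, InputValidationError
from .inputs import BaseCase, Cohort, StrategyInputs


@dataclass(frozen=True)
class CostSpec:
    """Cost inputs for a synthetic strategy, with an optional relative jitter
    applied when a base case is materialised."""

    monthly_drug_cost: float = 15_000.0
    ae_cost: float = 8_000.0
    monitoring_cost: float = 3_000.0
    referent_monitoring_cost: float = 3_000.0
    relative_jitter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("monthly_drug_cost", "ae_cost", "monitoring_cost",
                     "referent_monitoring_cost"):
            if getattr(self, name) < 0:
                raise InputValidationError(f"{name} must be nonnegative")
        if not 0 <= self.relative_jitter < 1:
            raise InputValidationError("relative_jitter must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic two-arm comparison.

    ``control_median_pfs`` is in months; ``hazard_ratio`` is treatment vs
    control (< 1 means the treatment delays progression);
    ``censoring_rate`` is the per-month dropout hazard (0 = administrative
    censoring at the horizon only).
    """

    cohort_size: int = 1000
    control_median_pfs: float = 14.0
    hazard_ratio: float = 0.5
    horizon_months: float = 24.0
    censoring_rate: float = 0.01
    cost_spec: CostSpec = field(default_factory=CostSpec)
    cohort: Cohort = Cohort.BRCA_VARIANT
    wtp: float = 100_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise InputValidationError("cohort_size must be at least 2")
        if self.control_median_pfs <= 0 or self.horizon_months <= 0:
            raise InputValidationError("medians and horizon must be positive")
        if self.hazard_ratio <= 0:
            raise InputValidationError("hazard_ratio must be positive")
        if self.censoring_rate < 0:
            raise InputValidationError("censoring_rate must be nonnegative")

    @property
    def control_hazard(self) -> float:
        return math.log(2.0) / self.control_median_pfs

    @property
    def treatment_hazard(self) -> float:
        return self.hazard_ratio * self.control_hazard


def _exponential_rmst_months(hazard: float, horizon: float) -> float:
    """Closed-form restricted mean of an exponential survival curve."""
    if hazard == 0:
        return horizon
    return (1.0 - math.exp(-hazard * horizon)) / hazard


def analytic_pf_advantage_years(spec: SyntheticSpec) -> float:
    """Restricted-mean progression-free gain implied by the spec (years)."""
    gain_months = (
        _exponential_rmst_months(spec.treatment_hazard, spec.horizon_months)
        - _exponential_rmst_months(spec.control_hazard, spec.horizon_months)
    )
    return gain_months / 12.0


def analytic_pfs24_probability(spec: SyntheticSpec) -> float:
    """Treatment-arm survival at 24 months under the exponential model."""
    return math.exp(-spec.treatment_hazard * min(24.0, spec.horizon_months))


def spec_for_target_advantage(advantage_years: float, **kwargs) -> SyntheticSpec:
    """Build a spec whose analytic restricted-mean gain equals a target.

    The gain over a horizon ``H`` is bounded above by ``H`` minus the
    control arm's restricted mean (even a treatment that never progresses
    cannot be progression-free for longer than the horizon), so a target
    beyond that bound raises :class:`InfeasibleAdvantageError` — e.g. a
    3-year advantage is not representable over a 24-month horizon.
    """
    base = SyntheticSpec(**kwargs)
    if advantage_years < 0:
        raise InputValidationError("advantage_years must be nonnegative")
    horizon = base.horizon_months
    control_rmst = _exponential_rmst_months(base.control_hazard, horizon)
    max_gain_months = horizon - control_rmst
    target_months = advantage_years * 12.0
    if target_months >= max_gain_months:
        raise InfeasibleAdvantageError(
            f"a {advantage_years:g}-year progression-free advantage exceeds the "
            f"largest restricted-mean gain representable over a {horizon:g}-month "
            f"horizon with this control arm ({max_gain_months / 12.0:.3f} years)"
        )
    if target_months == 0:
        return replace(base, hazard_ratio=1.0)

    def gap(hr: float) -> float:
        return (_exponential_rmst_months(hr * base.control_hazard, horizon)
                - control_rmst - target_months)

    hr = brentq(gap, 1e-12, 1.0, xtol=1e-12)
    return replace(base, hazard_ratio=float(hr))


def simulate_event_times(spec: SyntheticSpec) -> pd.DataFrame:
    """Patient-level progression/censoring times for both arms.

    Columns: arm ('control'/'treatment'), time (months, observed),
    event (1 = progression observed, 0 = censored).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm, hazard in (("control", spec.control_hazard),
                        ("treatment", spec.treatment_hazard)):
        n = spec.cohort_size
        event_t = (rng.exponential(1.0 / hazard, n) if hazard > 0
                   else np.full(n, np.inf))
        censor_t = (rng.exponential(1.0 / spec.censoring_rate, n)
                    if spec.censoring_rate > 0 else np.full(n, np.inf))
        censor_t = np.minimum(censor_t, spec.horizon_months)
        observed = np.minimum(event_t, censor_t)
        frames.append(pd.DataFrame({
            "arm": arm,
            "time": observed,
            "event": (event_t <= censor_t).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def _km_curve(times: np.ndarray, events: np.ndarray, horizon: float) -> SurvivalCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    knot_times = sf.index.to_numpy(dtype=float)
    probs = sf.iloc[:, 0].to_numpy(dtype=float)
    if knot_times[0] != 0.0:
        knot_times = np.insert(knot_times, 0, 0.0)
        probs = np.insert(probs, 0, 1.0)
    # extend follow-up to the horizon (administrative censoring guarantees
    # the estimate is flat beyond the last observed time <= horizon)
    if knot_times[-1] < horizon:
        knot_times = np.append(knot_times, horizon)
        probs = np.append(probs, probs[-1])
    return SurvivalCurve(times=knot_times, probabilities=probs)


def simulate_km_curves(spec: SyntheticSpec) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Product-limit curves (control, treatment) from one simulated trial."""
    data = simulate_event_times(spec)
    curves = []
    for arm in ("control", "treatment"):
        sub = data[data["arm"] == arm]
        curves.append(_km_curve(sub["time"].to_numpy(), sub["event"].to_numpy(),
                                spec.horizon_months))
    return curves[0], curves[1]


def synthetic_base_case(spec: SyntheticSpec) -> BaseCase:
    """Materialise one simulated comparison as an analysable base case.

    The treatment strategy's 24-month progression-free probability is read
    off the treatment Kaplan-Meier curve, its advantage is the
    restricted-mean difference between the arms, and costs come from the
    cost specification (independently jittered within
    ``relative_jitter`` when that is nonzero).
    """
    control, treatment = simulate_km_curves(spec)
    horizon = spec.horizon_months
    advantage_years = (restricted_mean_pf_years(treatment, horizon)
                       - restricted_mean_pf_years(control, horizon))
    p24 = treatment.probability_at(min(24.0, horizon))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    cs = spec.cost_spec

    def jitter(value: float) -> float:
        if cs.relative_jitter == 0 or value == 0:
            return value
        return float(value * rng.uniform(1 - cs.relative_jitter, 1 + cs.relative_jitter))

    treatment_strategy = StrategyInputs(
        name="synthetic_treatment",
        monthly_drug_cost=jitter(cs.monthly_drug_cost),
        months_on_drug=horizon,
        ae_cost=jitter(cs.ae_cost),
        monitoring_cost=jitter(cs.monitoring_cost),
        pfs_advantage_years=max(0.0, advantage_years),
        pfs24_probability=p24,
    )
    referent = StrategyInputs(
        name="no_maintenance",
        monitoring_cost=cs.referent_monitoring_cost,
    )
    return BaseCase(
        cohort=spec.cohort,
        referent=referent,
        comparators=(treatment_strategy,),
        horizon_months=horizon,
        wtp=spec.wtp,
    )
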