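"""Probabilistic sensitivity analysis by microsimulation.

Each simulated patient receives an independently sampled parameter set —
drug acquisition costs varied over a +/-50% relative range, adverse-event
costs +/-50%, and progression-free survival advantage and 24-month
progression-free probability +/-10%, mirroring the one-way ranges — and is
pushed through the deterministic cost and effectiveness engine to yield a
patient-level ICER versus the fixed no-maintenance referent. Trials are
batches of patients; the headline summary is the fraction of patients whose
ICER is at or below the willingness-to-pay threshold, plus the
cost-effectiveness acceptability curve (CEAC) over a WTP grid.

The distribution family over each range defaults to uniform (the least
informative choice over a stated interval); triangular with the input value
as mode is available. Zero-width ranges collapse every sample to the
deterministic inputs exactly, so the degenerate PSA reproduces the
deterministic ICERs — that equivalence is the verifiable contract of the
microsimulation design.

Strategies carried as published totals (bevacizumab) expose only their
cost override and PF-LYS override; the cost range is applied to the
override total and the PFS range once to the PF-LYS override.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import total_cost
from .engine import pf_lys
from .errors import InputValidationError, UnknownParameterError
from .inputs import (
    COST_RELATIVE_RANGE,
    PFS_RELATIVE_RANGE,
    BaseCase,
    StrategyInputs,
)


class DistributionFamily(enum.Enum):
    UNIFORM = "uniform"
    TRIANGULAR = "triangular"


#: Parameters a distribution specification may name, with the default
#: relative half-width applied to each.
DEFAULT_DISTRIBUTIONS: dict[str, float] = {
    "monthly_drug_cost": COST_RELATIVE_RANGE,
    "ae_cost": COST_RELATIVE_RANGE,
    "total_cost_override": COST_RELATIVE_RANGE,
    "pfs_advantage_years": PFS_RELATIVE_RANGE,
    "pfs24_probability": PFS_RELATIVE_RANGE,
    "pf_lys_override": PFS_RELATIVE_RANGE,
}


@dataclass(frozen=True)
class PSAConfig:
    """Monte-Carlo design: trial/patient counts, ranges, family, seed."""

    n_trials: int = 1000
    n_patients: int = 1000
    distributions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )
    distribution_family: DistributionFamily = DistributionFamily.UNIFORM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_patients <= 0:
            raise InputValidationError("n_trials and n_patients must be positive")
        unknown = set(self.distributions) - set(DEFAULT_DISTRIBUTIONS)
        if unknown:
            raise UnknownParameterError(
                f"unknown parameter(s) in distributions: {sorted(unknown)}; "
                f"known: {sorted(DEFAULT_DISTRIBUTIONS)}"
            )
        for key, width in self.distributions.items():
            if width < 0:
                raise InputValidationError(f"distribution range for {key} must be >= 0")

    def range_for(self, parameter: str) -> float:
        return self.distributions.get(parameter, 0.0)


@dataclass(frozen=True)
class PSAResult:
    """Sampled ICERs and cost-effectiveness fractions for one base case."""

    wtp: float
    n_trials: int
    n_patients: int
    #: strategy name -> array of shape (n_trials, n_patients); NaN = undefined ICER
    icer_samples: dict[str, np.ndarray]
    #: fraction of all patients with a defined ICER <= the WTP threshold
    fraction_ce_at_wtp: dict[str, float]

    def trial_mean_icers(self) -> pd.DataFrame:
        """Per-trial mean ICER per strategy (rows = trials)."""
        return pd.DataFrame(
            {name: np.nanmean(s, axis=1) for name, s in self.icer_samples.items()}
        )


def _sample(rng: np.random.Generator, base: float, rel_range: float,
            family: DistributionFamily, size: int) -> np.ndarray:
    """Draw from the declared family over base x (1 +/- rel_range).

    A zero width (or zero base) returns the base value exactly, so
    degenerate configurations collapse to the deterministic model.
    """
    if rel_range == 0.0 or base == 0.0:
        return np.full(size, base)
    lo, hi = base * (1 - rel_range), base * (1 + rel_range)
    if family is DistributionFamily.UNIFORM:
        return rng.uniform(lo, hi, size)
    return rng.triangular(lo, base, hi, size)


def _sample_strategy(strategy: StrategyInputs, referent_total: float,
                     config: PSAConfig, rng: np.random.Generator,
                     size: int) -> np.ndarray:
    """Patient-level ICER samples for one strategy (NaN where undefined)."""
    family = config.distribution_family
    if strategy.total_cost_override is not None:
        cost = _sample(rng, strategy.total_cost_override,
                       config.range_for("total_cost_override"), family, size)
    else:
        monthly = _sample(rng, strategy.monthly_drug_cost,
                          config.range_for("monthly_drug_cost"), family, size)
        ae = _sample(rng, strategy.ae_cost, config.range_for("ae_cost"), family, size)
        cost = strategy.months_on_drug * monthly + ae + strategy.monitoring_cost
    if strategy.pf_lys_override is not None:
        eff = _sample(rng, strategy.pf_lys_override,
                      config.range_for("pf_lys_override"), family, size)
    else:
        adv = _sample(rng, strategy.pfs_advantage_years,
                      config.range_for("pfs_advantage_years"), family, size)
        p24 = np.clip(
            _sample(rng, strategy.pfs24_probability,
                    config.range_for("pfs24_probability"), family, size),
            0.0, 1.0,
        )
        eff = adv * p24
    inc_cost = cost - referent_total
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(eff > 0, inc_cost / eff, np.nan)
    return icers


def run_psa(base_case: BaseCase, config: PSAConfig) -> PSAResult:
    """Microsimulate every comparator of a base case.

    Deterministic given ``config.seed``: one child random stream per
    strategy (spawned in comparator order), all trials and patients drawn
    vectorized from that stream. The referent's cost is held fixed; its
    PF-LYS is zero by invariant.
    """
    referent_total = total_cost(base_case.referent).total
    if pf_lys(base_case.referent) != 0:
        raise InputValidationError("referent must have zero PF-LYS")
    size = config.n_trials * config.n_patients
    streams = np.random.SeedSequence(config.seed).spawn(len(base_case.comparators))
    icer_samples: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    for strategy, stream in zip(base_case.comparators, streams):
        rng = np.random.default_rng(stream)
        samples = _sample_strategy(strategy, referent_total, config, rng, size)
        samples = samples.reshape(config.n_trials, config.n_patients)
        icer_samples[strategy.name] = samples
        defined = ~np.isnan(samples)
        fractions[strategy.name] = float(
            np.mean(defined & (samples <= base_case.wtp))
        )
    return PSAResult(
        wtp=base_case.wtp,
        n_trials=config.n_trials,
        n_patients=config.n_patients,
        icer_samples=icer_samples,
        fraction_ce_at_wtp=fractions,
    )


def ceac(result: PSAResult, wtp_grid: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each WTP in the grid and each strategy, the fraction of sampled
    patients with a defined ICER at or below that WTP. Nondecreasing in WTP
    by construction.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise InputValidationError("wtp_grid must be nonempty")
    table = {}
    for name, samples in result.icer_samples.items():
        flat = samples.ravel()
        defined = flat[~np.isnan(flat)]
        table[name] = [float(np.count_nonzero(defined <= w)) / flat.size for w in grid]
    return pd.DataFrame(table, index=pd.Index(grid, name="wtp"))
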