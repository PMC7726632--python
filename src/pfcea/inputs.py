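"""Domain types and model inputs for the maintenance-therapy cost-effectiveness model.

The model compares frontline maintenance strategies for advanced epithelial
ovarian cancer (PARP inhibitors and/or bevacizumab) against no maintenance,
over a 24-month horizon, separately for three molecular cohorts: *BRCA*
variant carriers, homologous-recombination-deficient *BRCA* wild-type
tumors, and homologous-recombination-proficient tumors.

Each strategy is described by a cost decomposition (monthly drug
acquisition price, a lump adverse-event cost, and a monitoring/
administration residual, all in undiscounted 2020 USD) and two efficacy
inputs: the progression-free survival advantage over no maintenance in
years, and the probability of remaining progression-free at 24 months.
Bevacizumab monotherapy is carried as published totals (a 24-month cost
override and a progression-free life-years-saved override) because its
component-level decomposition is not publicly printed.

:func:`reference_base_cases` returns the three published cohorts populated
with these inputs; :func:`load_config` / :func:`save_config` round-trip the
same structure through a YAML configuration file.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigSchemaError, InputValidationError

logger = logging.getLogger(__name__)

HORIZON_MONTHS = 24.0
WTP_PER_PF_LYS = 100_000.0

#: Relative ranges used by the published sensitivity analyses:
#: cost parameters varied by +/-50%, progression-free survival quantities
#: (advantage and 24-month probability) by +/-10%.
COST_RELATIVE_RANGE = 0.50
PFS_RELATIVE_RANGE = 0.10


class Cohort(enum.Enum):
    """Molecular signature defining a base-case cohort."""

    BRCA_VARIANT = "brca_variant"
    HRD_BRCA_WT = "hrd_brca_wt"
    HR_PROFICIENT = "hr_proficient"

    @property
    def label(self) -> str:
        return {
            Cohort.BRCA_VARIANT: "BRCA variant",
            Cohort.HRD_BRCA_WT: "Homologous recombination deficient, BRCA wild type",
            Cohort.HR_PROFICIENT: "Homologous recombination proficient",
        }[self]


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InputValidationError(f"{name} must be a finite nonnegative number, got {value!r}")


@dataclass(frozen=True)
class StrategyInputs:
    """One maintenance regimen's cost decomposition and efficacy inputs.

    Costs are totals over the model horizon except ``monthly_drug_cost``,
    which is charged once per monthly cycle for ``months_on_drug`` cycles.
    ``total_cost_override`` and ``pf_lys_override``, when set, replace the
    additive cost computation and the multiplicative effectiveness formula
    respectively (used for regimens whose decomposition is not published).
    """

    name: str
    monthly_drug_cost: float = 0.0
    months_on_drug: float = 0.0
    ae_cost: float = 0.0
    monitoring_cost: float = 0.0
    total_cost_override: float | None = None
    pfs_advantage_years: float = 0.0
    pfs24_probability: float = 0.0
    pf_lys_override: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise InputValidationError("strategy name must be a nonempty string")
        for fname in ("monthly_drug_cost", "ae_cost", "monitoring_cost", "months_on_drug"):
            _require_nonnegative(fname, getattr(self, fname))
        if self.total_cost_override is not None:
            _require_nonnegative("total_cost_override", self.total_cost_override)
        if not 0.0 <= self.pfs24_probability <= 1.0:
            raise InputValidationError(
                f"pfs24_probability must lie in [0, 1], got {self.pfs24_probability!r}"
            )
        if not math.isfinite(self.pfs_advantage_years):
            raise InputValidationError("pfs_advantage_years must be finite")
        if self.total_cost_override is not None:
            additive = (
                self.months_on_drug * self.monthly_drug_cost
                + self.ae_cost
                + self.monitoring_cost
            )
            if additive > 0 and not math.isclose(additive, self.total_cost_override):
                logger.info(
                    "strategy %s: total_cost_override %.2f wins over additive "
                    "components summing to %.2f",
                    self.name,
                    self.total_cost_override,
                    additive,
                )

    @property
    def has_cost_decomposition(self) -> bool:
        return self.total_cost_override is None


@dataclass(frozen=True)
class BaseCase:
    """A molecular cohort with a no-maintenance referent and comparators."""

    cohort: Cohort
    referent: StrategyInputs
    comparators: tuple[StrategyInputs, ...]
    horizon_months: float = HORIZON_MONTHS
    wtp: float = WTP_PER_PF_LYS

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparators", tuple(self.comparators))
        if self.horizon_months <= 0:
            raise InputValidationError("horizon_months must be positive")
        if self.wtp <= 0:
            raise InputValidationError("wtp must be positive")
        if self.referent.pfs_advantage_years != 0 or self.referent.monthly_drug_cost != 0:
            raise InputValidationError(
                "referent must have pfs_advantage_years = 0 and monthly_drug_cost = 0"
            )
        names = [s.name for s in self.comparators]
        if len(set(names)) != len(names):
            raise InputValidationError(f"comparator names must be unique, got {names}")
        for s in (self.referent, *self.comparators):
            if s.months_on_drug > self.horizon_months:
                raise InputValidationError(
                    f"strategy {s.name}: months_on_drug {s.months_on_drug} exceeds "
                    f"horizon {self.horizon_months}"
                )

    def strategy(self, name: str) -> StrategyInputs:
        for s in self.comparators:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Published model constants
# ---------------------------------------------------------------------------
# Monthly acquisition prices per 28/30-day cycle (2020 wholesale acquisition
# cost for the oral PARP inhibitors; the combination price is the combined
# olaparib + bevacizumab monthly cost).
OLAPARIB_MONTHLY_PRICE = 16_999.0
NIRAPARIB_MONTHLY_PRICE = 19_947.0
OLAPARIB_BEV_COMBINED_MONTHLY_PRICE = 22_249.0

# Lump adverse-event treatment costs over the horizon.
OLAPARIB_AE_COST = 7_817.0
OLAPARIB_BEV_AE_COST = 6_430.0
NIRAPARIB_AE_COST = 10_447.0

# 24-month totals per strategy (drug + administration + monitoring + AEs).
NO_MAINTENANCE_TOTAL = 3_051.0
OLAPARIB_TOTAL = 418_848.0
OLAPARIB_BEV_TOTAL = 545_758.0
BEVACIZUMAB_TOTAL = 133_591.0
NIRAPARIB_TOTAL = 492_226.0

# Monitoring/administration residuals, back-derived as
# total - 24 x monthly price - AE cost; they subsume office visits, labs,
# CA-125 testing and (for the combination) infusion administration.
OLAPARIB_MONITORING = OLAPARIB_TOTAL - 24 * OLAPARIB_MONTHLY_PRICE - OLAPARIB_AE_COST
NIRAPARIB_MONITORING = NIRAPARIB_TOTAL - 24 * NIRAPARIB_MONTHLY_PRICE - NIRAPARIB_AE_COST
OLAPARIB_BEV_MONITORING = (
    OLAPARIB_BEV_TOTAL - 24 * OLAPARIB_BEV_COMBINED_MONTHLY_PRICE - OLAPARIB_BEV_AE_COST
)

# Efficacy inputs per cohort: (PFS advantage in years, 24-month PFS probability).
EFFICACY: dict[Cohort, dict[str, tuple[float, float]]] = {
    Cohort.BRCA_VARIANT: {
        "olaparib": (3.01, 0.74),
        "olaparib_bevacizumab": (1.95, 0.76),
        "niraparib": (0.93, 0.49),
    },
    Cohort.HRD_BRCA_WT: {
        "olaparib_bevacizumab": (1.66, 0.52),
        "niraparib": (0.95, 0.48),
    },
    Cohort.HR_PROFICIENT: {
        "olaparib_bevacizumab": (0.93, 0.27),
        "niraparib": (0.23, 0.2),
    },
}

# Bevacizumab monotherapy: only published totals are available, carried as
# overrides (incremental PF-LYS vs no maintenance, per cohort).
BEVACIZUMAB_PF_LYS: dict[Cohort, float] = {
    Cohort.BRCA_VARIANT: 0.26,
    Cohort.HRD_BRCA_WT: 0.18,
    Cohort.HR_PROFICIENT: 0.23,
}


def _no_maintenance() -> StrategyInputs:
    return StrategyInputs(name="no_maintenance", monitoring_cost=NO_MAINTENANCE_TOTAL)


def _bevacizumab(cohort: Cohort) -> StrategyInputs:
    return StrategyInputs(
        name="bevacizumab",
        total_cost_override=BEVACIZUMAB_TOTAL,
        pf_lys_override=BEVACIZUMAB_PF_LYS[cohort],
    )


def _oral_strategy(name: str, monthly: float, ae: float, monitoring: float,
                   cohort: Cohort) -> StrategyInputs:
    adv, p24 = EFFICACY[cohort][name]
    return StrategyInputs(
        name=name,
        monthly_drug_cost=monthly,
        months_on_drug=HORIZON_MONTHS,
        ae_cost=ae,
        monitoring_cost=monitoring,
        pfs_advantage_years=adv,
        pfs24_probability=p24,
    )


def reference_base_cases(wtp: float = WTP_PER_PF_LYS) -> list[BaseCase]:
    """The three published cohorts populated with the reference constants.

    Base case 1 (*BRCA* variant) carries five strategies including olaparib
    monotherapy; base cases 2 and 3 carry four (olaparib monotherapy was not
    studied outside the *BRCA*-variant population).
    """
    cases: list[BaseCase] = []
    for cohort in Cohort:
        comparators: list[StrategyInputs] = []
        if cohort is Cohort.BRCA_VARIANT:
            comparators.append(
                _oral_strategy("olaparib", OLAPARIB_MONTHLY_PRICE, OLAPARIB_AE_COST,
                               OLAPARIB_MONITORING, cohort)
            )
        comparators.append(
            _oral_strategy("olaparib_bevacizumab", OLAPARIB_BEV_COMBINED_MONTHLY_PRICE,
                           OLAPARIB_BEV_AE_COST, OLAPARIB_BEV_MONITORING, cohort)
        )
        comparators.append(_bevacizumab(cohort))
        comparators.append(
            _oral_strategy("niraparib", NIRAPARIB_MONTHLY_PRICE, NIRAPARIB_AE_COST,
                           NIRAPARIB_MONITORING, cohort)
        )
        cases.append(
            BaseCase(cohort=cohort, referent=_no_maintenance(),
                     comparators=tuple(comparators), horizon_months=HORIZON_MONTHS,
                     wtp=wtp)
        )
    return cases


# ---------------------------------------------------------------------------
# Configuration file round-trip
# ---------------------------------------------------------------------------
_STRATEGY_KEYS = {
    "name": True,  # required
    "monthly_drug_cost": False,
    "months_on_drug": False,
    "ae_cost": False,
    "monitoring_cost": False,
    "total_cost_override": False,
    "pfs_advantage_years": False,
    "pfs24_probability": False,
    "pf_lys_override": False,
}
_BASE_CASE_KEYS = {"cohort": True, "referent": True, "comparators": True}
_TOP_KEYS = {"horizon_months": False, "wtp": False, "base_cases": True, "sensitivity": False}
_SENSITIVITY_KEYS = {"cost_relative_range": False, "pfs_relative_range": False}


def _check_keys(mapping: Mapping[str, Any], schema: Mapping[str, bool], context: str) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigSchemaError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - set(schema)
    if unknown:
        raise ConfigSchemaError(f"{context}: unknown key(s) {sorted(unknown)}")
    for key, required in schema.items():
        if required and key not in mapping:
            raise ConfigSchemaError(f"{context}: missing required field '{key}'")


def _strategy_from_dict(d: Mapping[str, Any], context: str) -> StrategyInputs:
    _check_keys(d, _STRATEGY_KEYS, context)
    return StrategyInputs(**d)


def _base_case_from_dict(d: Mapping[str, Any], horizon: float, wtp: float,
                         index: int) -> BaseCase:
    context = f"base_cases[{index}]"
    _check_keys(d, _BASE_CASE_KEYS, context)
    try:
        cohort = Cohort(d["cohort"])
    except ValueError as exc:
        raise ConfigSchemaError(
            f"{context}: unknown cohort {d['cohort']!r}; expected one of "
            f"{[c.value for c in Cohort]}"
        ) from exc
    referent = _strategy_from_dict(d["referent"], f"{context}.referent")
    raw_comparators = d["comparators"]
    if raw_comparators is None:
        raw_comparators = []
    if not isinstance(raw_comparators, Sequence) or isinstance(raw_comparators, (str, bytes)):
        raise ConfigSchemaError(f"{context}.comparators: expected a list")
    comparators = tuple(
        _strategy_from_dict(c, f"{context}.comparators[{i}]")
        for i, c in enumerate(raw_comparators)
    )
    return BaseCase(cohort=cohort, referent=referent, comparators=comparators,
                    horizon_months=horizon, wtp=wtp)


def load_config(path: str | Path) -> list[BaseCase]:
    """Read base cases from a YAML configuration file.

    Unknown keys are rejected at every level; missing required fields raise
    :class:`ConfigSchemaError` naming the field; invariant violations raise
    :class:`InputValidationError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    _check_keys(raw, _TOP_KEYS, "config")
    horizon = float(raw.get("horizon_months", HORIZON_MONTHS))
    wtp = float(raw.get("wtp", WTP_PER_PF_LYS))
    if "sensitivity" in raw:
        _check_keys(raw["sensitivity"], _SENSITIVITY_KEYS, "config.sensitivity")
    cases_raw = raw["base_cases"]
    if not isinstance(cases_raw, Sequence):
        raise ConfigSchemaError("config.base_cases: expected a list")
    return [_base_case_from_dict(d, horizon, wtp, i) for i, d in enumerate(cases_raw)]


def load_sensitivity_ranges(path: str | Path) -> dict[str, float]:
    """Read the optional sensitivity-range block of a configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    _check_keys(raw, _TOP_KEYS, "config")
    sens = dict(raw.get("sensitivity", {}))
    _check_keys(sens, _SENSITIVITY_KEYS, "config.sensitivity")
    return {
        "cost_relative_range": float(sens.get("cost_relative_range", COST_RELATIVE_RANGE)),
        "pfs_relative_range": float(sens.get("pfs_relative_range", PFS_RELATIVE_RANGE)),
    }


def _strategy_to_dict(s: StrategyInputs) -> dict[str, Any]:
    d: dict[str, Any] = {"name": s.name}
    for key in ("monthly_drug_cost", "months_on_drug", "ae_cost", "monitoring_cost",
                "pfs_advantage_years", "pfs24_probability"):
        value = getattr(s, key)
        if value != 0.0:
            d[key] = value
    if s.total_cost_override is not None:
        d["total_cost_override"] = s.total_cost_override
    if s.pf_lys_override is not None:
        d["pf_lys_override"] = s.pf_lys_override
    return d


def to_config_dict(base_cases: Iterable[BaseCase]) -> dict[str, Any]:
    cases = list(base_cases)
    if not cases:
        return {"base_cases": []}
    horizons = {c.horizon_months for c in cases}
    wtps = {c.wtp for c in cases}
    if len(horizons) != 1 or len(wtps) != 1:
        raise InputValidationError(
            "all base cases in one configuration must share horizon_months and wtp"
        )
    return {
        "horizon_months": cases[0].horizon_months,
        "wtp": cases[0].wtp,
        "base_cases": [
            {
                "cohort": c.cohort.value,
                "referent": _strategy_to_dict(c.referent),
                "comparators": [_strategy_to_dict(s) for s in c.comparators],
            }
            for c in cases
        ],
    }


def save_config(base_cases: Iterable[BaseCase], path: str | Path) -> None:
    """Serialize base cases to the YAML schema read by :func:`load_config`."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(to_config_dict(base_cases), fh, sort_keys=False)


def reference_config_path() -> Path:
    """Path of the bundled reference configuration file."""
    return Path(__file__).parent / "data" / "reference.yaml"
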