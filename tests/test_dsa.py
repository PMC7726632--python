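"""Deterministic sensitivity analysis: closed-form thresholds, NR semantics,
round-trip consistency, bisection agreement, and one-way ranges."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pfcea import (
    Cohort,
    ParameterNotApplicableError,
    StrategyInputs,
    ThresholdParameter,
    bisection_threshold,
    one_way_range,
    pf_lys,
    solve_ae_cost_threshold,
    solve_pfs_advantage_threshold,
    solve_pfs_probability_threshold,
    solve_price_threshold,
)
from pfcea.dsa import icer_at

WTP = 100_000.0

# (cohort, strategy, expected threshold) frozen from the closed forms:
# P* = (wtp x dPF-LYS - (ae + monitoring - referent total)) / 24
PRICE_CASES = [
    (Cohort.BRCA_VARIANT, "olaparib", 8954.9583333333),
    (Cohort.BRCA_VARIANT, "olaparib_bevacizumab", 5811.2083333333),
    (Cohort.HRD_BRCA_WT, "olaparib_bevacizumab", 3232.8750),
    (Cohort.HR_PROFICIENT, "olaparib_bevacizumab", 682.4583333333),
    (Cohort.BRCA_VARIANT, "niraparib", 1463.4583333333),
    (Cohort.HRD_BRCA_WT, "niraparib", 1464.7083333333),
]

# D* = incremental cost / (wtp x p24), frozen from the closed form
ADVANTAGE_CASES = [
    (Cohort.BRCA_VARIANT, "olaparib", 5.62),
    (Cohort.BRCA_VARIANT, "olaparib_bevacizumab", 7.14),
    (Cohort.HRD_BRCA_WT, "olaparib_bevacizumab", 10.44),
    (Cohort.HR_PROFICIENT, "olaparib_bevacizumab", 20.10),
    (Cohort.BRCA_VARIANT, "niraparib", 9.98),
    (Cohort.HRD_BRCA_WT, "niraparib", 10.19),
    (Cohort.HR_PROFICIENT, "niraparib", 24.46),
]

ORAL_PAIRS = [(cohort, name) for cohort, name, _ in PRICE_CASES] + [
    (Cohort.HR_PROFICIENT, "niraparib")
]


class TestPriceThresholds:
    @pytest.mark.parametrize(("cohort", "name", "expected"), PRICE_CASES)
    def test_closed_form_values(self, ref_cases, cohort, name, expected):
        bc = ref_cases[cohort]
        r = solve_price_threshold(bc.strategy(name), bc.referent, bc.wtp)
        assert r.threshold_value == pytest.approx(expected, rel=1e-9)

    def test_niraparib_unreachable_in_hr_proficient_cohort(self, hrp):
        """Even a free drug cannot clear the threshold at a 0.046-year gain."""
        r = solve_price_threshold(hrp.strategy("niraparib"), hrp.referent, hrp.wtp)
        assert r.not_reachable and r.threshold_value is None

    def test_component_price_within_combination(self, ref_cases):
        """Varying only the olaparib share of the combined monthly cost,
        holding the bevacizumab share fixed."""
        brca = ref_cases[Cohort.BRCA_VARIANT]
        r = solve_price_threshold(
            brca.strategy("olaparib_bevacizumab"), brca.referent, brca.wtp,
            component_cost=16_999.0)
        assert r.threshold_value == pytest.approx(561.2083333333, rel=1e-9)
        for cohort in (Cohort.HRD_BRCA_WT, Cohort.HR_PROFICIENT):
            bc = ref_cases[cohort]
            r = solve_price_threshold(
                bc.strategy("olaparib_bevacizumab"), bc.referent, bc.wtp,
                component_cost=16_999.0)
            assert r.not_reachable

    def test_override_strategy_has_no_price_parameter(self, brca):
        with pytest.raises(ParameterNotApplicableError):
            solve_price_threshold(brca.strategy("bevacizumab"), brca.referent, brca.wtp)

    def test_zero_months_on_drug_not_applicable(self, brca):
        s = StrategyInputs(name="x", monthly_drug_cost=100.0, months_on_drug=0.0,
                           pfs_advantage_years=1.0, pfs24_probability=0.5)
        with pytest.raises(ParameterNotApplicableError):
            solve_price_threshold(s, brca.referent, WTP)


class TestAdvantageThresholds:
    @pytest.mark.parametrize(("cohort", "name", "expected"), ADVANTAGE_CASES)
    def test_closed_form_values_to_two_decimals(self, ref_cases, cohort, name, expected):
        bc = ref_cases[cohort]
        r = solve_pfs_advantage_threshold(bc.strategy(name), bc.referent, bc.wtp)
        assert round(r.threshold_value, 2) == expected

    def test_zero_incremental_cost_gives_zero_threshold(self, brca):
        s = StrategyInputs(name="free", monitoring_cost=3051.0,
                           pfs_advantage_years=1.0, pfs24_probability=0.5)
        r = solve_pfs_advantage_threshold(s, brca.referent, WTP)
        assert r.threshold_value == 0.0

    def test_zero_probability_is_unreachable(self, brca):
        s = StrategyInputs(name="x", monthly_drug_cost=100.0, months_on_drug=24.0,
                           pfs_advantage_years=1.0, pfs24_probability=0.0)
        assert solve_pfs_advantage_threshold(s, brca.referent, WTP).not_reachable


class TestProbabilityThresholds:
    @pytest.mark.parametrize(("cohort", "name"), ORAL_PAIRS)
    def test_all_fixture_cells_unreachable(self, ref_cases, cohort, name):
        """Even certain progression-free status at 24 months cannot offset
        the incremental cost for any fixture strategy."""
        bc = ref_cases[cohort]
        r = solve_pfs_probability_threshold(bc.strategy(name), bc.referent, bc.wtp)
        assert r.not_reachable

    def test_hypothetical_direct_division(self, brca):
        s = StrategyInputs(name="x", monthly_drug_cost=(50_000.0 + 3051.0) / 24,
                           months_on_drug=24.0, pfs_advantage_years=1.0,
                           pfs24_probability=0.9)
        r = solve_pfs_probability_threshold(s, brca.referent, WTP)
        assert r.threshold_value == pytest.approx(0.5, rel=1e-9)

    def test_zero_advantage_is_unreachable(self, brca):
        s = StrategyInputs(name="x", pfs24_probability=0.5)
        assert solve_pfs_probability_threshold(s, brca.referent, WTP).not_reachable


class TestAECostThresholds:
    @pytest.mark.parametrize(("cohort", "name"), ORAL_PAIRS)
    def test_all_fixture_cells_unreachable(self, ref_cases, cohort, name):
        bc = ref_cases[cohort]
        r = solve_ae_cost_threshold(bc.strategy(name), bc.referent, bc.wtp)
        assert r.not_reachable

    def test_cheap_drug_has_finite_ae_threshold(self, brca):
        s = StrategyInputs(name="cheap", monthly_drug_cost=100.0, months_on_drug=24.0,
                           ae_cost=60_000.0, monitoring_cost=3051.0,
                           pfs_advantage_years=1.0, pfs24_probability=0.8)
        r = solve_ae_cost_threshold(s, brca.referent, WTP)
        assert r.threshold_value == pytest.approx(
            WTP * 0.8 - (2400.0 + 3051.0 - 3051.0), rel=1e-9)


def _all_defined_thresholds(ref_cases):
    for cohort, bc in ref_cases.items():
        for name in ("olaparib", "olaparib_bevacizumab", "niraparib"):
            try:
                strategy = bc.strategy(name)
            except KeyError:
                continue
            for solver, parameter in [
                (solve_price_threshold, ThresholdParameter.COMBINED_MONTHLY_COST),
                (solve_ae_cost_threshold, ThresholdParameter.AE_COST),
                (solve_pfs_advantage_threshold, ThresholdParameter.PFS_ADVANTAGE),
                (solve_pfs_probability_threshold, ThresholdParameter.PFS24_PROBABILITY),
            ]:
                result = solver(strategy, bc.referent, bc.wtp)
                yield bc, strategy, parameter, result


class TestRoundTripAndBisection:
    def test_defined_thresholds_round_trip_to_wtp(self, ref_cases):
        """Substituting any defined threshold back gives ICER = WTP to 1e-6."""
        checked = 0
        for bc, strategy, parameter, result in _all_defined_thresholds(ref_cases):
            if result.not_reachable:
                continue
            value = icer_at(strategy, bc.referent, bc.wtp, parameter,
                            result.threshold_value)
            assert value == pytest.approx(bc.wtp, rel=1e-6)
            checked += 1
        assert checked >= 8  # every defined fixture threshold was exercised

    def test_bisection_agrees_with_closed_forms(self, ref_cases):
        for bc, strategy, parameter, result in _all_defined_thresholds(ref_cases):
            numeric = bisection_threshold(strategy, bc.referent, bc.wtp, parameter)
            assert numeric.not_reachable == result.not_reachable
            if not result.not_reachable:
                assert numeric.threshold_value == pytest.approx(
                    result.threshold_value, rel=1e-6, abs=1e-6)

    def test_nr_means_icer_exceeds_wtp_at_domain_boundary(self, ref_cases):
        """NR iff the best admissible value (price 0, AE 0, probability 1)
        still leaves the ICER above the willingness-to-pay threshold."""
        boundary = {
            ThresholdParameter.COMBINED_MONTHLY_COST: 0.0,
            ThresholdParameter.AE_COST: 0.0,
            ThresholdParameter.PFS24_PROBABILITY: 1.0,
        }
        for bc, strategy, parameter, result in _all_defined_thresholds(ref_cases):
            if parameter not in boundary:
                continue
            at_best = icer_at(strategy, bc.referent, bc.wtp, parameter,
                              boundary[parameter])
            assert result.not_reachable == (at_best > bc.wtp)


class TestOneWayRanges:
    def test_zero_width_range_collapses_to_base_icer(self, brca):
        s = brca.strategy("olaparib")
        r = one_way_range(s, brca.referent, ThresholdParameter.COMBINED_MONTHLY_COST,
                          0.0, brca.wtp)
        assert r.low_icer == r.high_icer == r.base_icer

    def test_niraparib_price_range_width(self, brca):
        """ICER width over a +/-50% price interval equals
        24 x monthly price / dPF-LYS exactly (affine structure)."""
        s = brca.strategy("niraparib")
        r = one_way_range(s, brca.referent, ThresholdParameter.COMBINED_MONTHLY_COST,
                          0.5, brca.wtp)
        expected = 24.0 * 19_947.0 / pf_lys(s)
        assert r.high_icer - r.low_icer == pytest.approx(expected, rel=1e-12)
        assert r.width == pytest.approx(1.05e6, rel=5e-3)

    @pytest.mark.parametrize(("cohort", "name"), ORAL_PAIRS)
    def test_ae_cost_is_the_least_sensitive_parameter(self, ref_cases, cohort, name):
        bc = ref_cases[cohort]
        s = bc.strategy(name)
        widths = {}
        for parameter, rel_range in [
            (ThresholdParameter.COMBINED_MONTHLY_COST, 0.5),
            (ThresholdParameter.AE_COST, 0.5),
            (ThresholdParameter.PFS_ADVANTAGE, 0.1),
            (ThresholdParameter.PFS24_PROBABILITY, 0.1),
        ]:
            widths[parameter] = one_way_range(s, bc.referent, parameter,
                                              rel_range, bc.wtp).width
        assert min(widths, key=widths.get) is ThresholdParameter.AE_COST

    def test_parameter_not_applicable_for_override_strategy(self, brca):
        with pytest.raises(ParameterNotApplicableError):
            one_way_range(brca.strategy("bevacizumab"), brca.referent,
                          ThresholdParameter.AE_COST, 0.5, brca.wtp)


@given(
    monthly=st.floats(100.0, 40_000.0),
    ae=st.floats(0.0, 20_000.0),
    monitoring=st.floats(0.0, 10_000.0),
    adv=st.floats(0.1, 5.0),
    p24=st.floats(0.05, 1.0),
)
def test_threshold_round_trip_property(monthly, ae, monitoring, adv, p24):
    """For random valid strategies, any defined threshold substituted back
    yields ICER = WTP within 1e-6 relative."""
    referent = StrategyInputs(name="ref", monitoring_cost=3051.0)
    s = StrategyInputs(name="s", monthly_drug_cost=monthly, months_on_drug=24.0,
                       ae_cost=ae, monitoring_cost=monitoring,
                       pfs_advantage_years=adv, pfs24_probability=p24)
    for solver, parameter in [
        (solve_price_threshold, ThresholdParameter.COMBINED_MONTHLY_COST),
        (solve_ae_cost_threshold, ThresholdParameter.AE_COST),
        (solve_pfs_advantage_threshold, ThresholdParameter.PFS_ADVANTAGE),
        (solve_pfs_probability_threshold, ThresholdParameter.PFS24_PROBABILITY),
    ]:
        result = solver(s, referent, WTP)
        if result.not_reachable or result.threshold_value == 0.0:
            continue
        back = icer_at(s, referent, WTP, parameter, result.threshold_value)
        assume(back is not None)
        assert back == pytest.approx(WTP, rel=1e-6)
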