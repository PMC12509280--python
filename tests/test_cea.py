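import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capscreen import (
    CEAConfig,
    build_canonical_strategies,
    cost_per_qaly,
    discounted_value,
    efficient_frontier,
    no_screening_run,
    percent_increase,
    percent_reduction,
    person_cost,
    person_qaly,
    run_strategy,
    strategy_outcomes,
    threshold_search,
)
from capscreen.cea import life_years_discounted
from capscreen.reference_tables import frontier_input_full_adherence
from capscreen.strategies import ADHERENCE_SCENARIOS

STRATEGIES = {s.name: s for s in build_canonical_strategies()}


class TestDiscounting:
    @pytest.mark.parametrize(
        "amount,age,ref,rate,expected",
        [
            (100.0, 55, 55, 0.03, 100.0),
            (100.0, 65, 55, 0.03, 100.0 * 1.03**-10),
            (100.0, 70, 55, 0.0, 100.0),
        ],
    )
    def test_discounted_value(self, amount, age, ref, rate, expected):
        assert discounted_value(amount, age, ref, rate) == pytest.approx(expected)

    def test_event_before_reference_rejected(self):
        with pytest.raises(ValueError):
            discounted_value(100.0, 50, 55, 0.03)

    def test_rate_zero_life_years_equal_death_age(self):
        d = np.array([40.0, 70.0, 100.0])
        assert np.allclose(life_years_discounted(d, 55, 0.0), d)

    def test_discounted_life_years_below_undiscounted(self):
        assert life_years_discounted(90.0, 55.0, 0.03) < 90.0
        assert life_years_discounted(50.0, 55.0, 0.03) == 50.0


class TestPersonAccounting:
    def test_qaly_without_events_equals_discounted_life_years(self, costs_utilities):
        _, utils = costs_utilities
        q = person_qaly(82.0, None, [], utils)
        assert q == pytest.approx(float(life_years_discounted(82.0, 55.0, 0.03)))

    def test_single_negative_colonoscopy_decrement(self, costs_utilities):
        _, utils = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        q0 = person_qaly(82.0, None, [], utils, cfg)
        q1 = person_qaly(82.0, None, [(60.0, "colonoscopy", 0)], utils, cfg)
        assert q0 - q1 == pytest.approx(0.0055)

    def test_stage_iv_terminal_year_decrement(self, costs_utilities):
        _, utils = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        dx = {"age": 70.0, "stage": 4, "death_age": 71.0, "death_cause": "crc"}
        q = person_qaly(71.0, dx, [], utils, cfg)
        # one year of life, terminal year dying of CRC: decrement 0.7
        assert 71.0 - q == pytest.approx(0.7)

    def test_single_fit_cost(self, costs_utilities):
        costs, _ = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        assert person_cost(None, [(60.0, "fit", 0)], costs, config=cfg) == pytest.approx(22.0)

    def test_stage_one_phase_arithmetic(self, costs_utilities):
        """Stage I, four years to other-cause death: initial + 2 ongoing + terminal."""
        costs, _ = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        dx = {"age": 70.0, "stage": 1, "death_age": 74.0, "death_cause": "other"}
        total = person_cost(dx, [], costs, config=cfg)
        assert total == pytest.approx(22_859 + 2 * 483 + 6_250)

    def test_short_survival_has_no_ongoing_phase(self, costs_utilities):
        costs, _ = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        dx = {"age": 70.0, "stage": 2, "death_age": 71.5, "death_cause": "crc"}
        total = person_cost(dx, [], costs, config=cfg)
        assert total == pytest.approx(19_415 + 24_859)  # initial + terminal

    def test_same_year_death_terminal_precedence(self, costs_utilities):
        costs, _ = costs_utilities
        cfg = CEAConfig(discount_rate=0.0)
        dx = {"age": 70.0, "stage": 4, "death_age": 70.4, "death_cause": "crc"}
        assert person_cost(dx, [], costs, config=cfg) == pytest.approx(35_513)

    def test_no_events_costs_nothing(self, costs_utilities):
        costs, _ = costs_utilities
        assert person_cost(None, [], costs) == 0.0

    def test_diagnosis_without_stage_rejected(self, costs_utilities):
        costs, _ = costs_utilities
        with pytest.raises(ValueError):
            person_cost({"age": 70.0}, [], costs)


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "baseline,scenario,expected",
        [(79, 49, 38.0), (36, 17, 52.8), (79, 53, 32.9), (36, 21, 41.7),
         (79, 46, 41.8), (36, 18, 50.0), (79, 29, 63.3), (36, 11, 69.4), (42, 42, 0.0)],
    )
    def test_percent_reduction(self, baseline, scenario, expected):
        assert percent_reduction(baseline, scenario) == expected

    def test_percent_reduction_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            percent_reduction(0, 10)

    def test_percent_increase(self):
        assert percent_increase(115, 155) == 34.8

    @pytest.mark.parametrize(
        "cost,qaly,expected",
        [(1_144_410, 73_770, 15.51), (3_178_861, 73_817, 43.06), (0.0, 10.0, 0.0)],
    )
    def test_cost_per_qaly(self, cost, qaly, expected):
        assert cost_per_qaly(cost, qaly) == expected

    def test_cost_per_qaly_requires_positive_qalys(self):
        with pytest.raises(ValueError):
            cost_per_qaly(100.0, 0.0)


class TestFrontier:
    def test_published_full_adherence_points(self):
        fr = efficient_frontier(frontier_input_full_adherence(), wtp=20_000)
        assert fr.frontier == ["biennial_fit47", "biennial_fit15", "colonoscopy_10y"]
        for name in ("biennial_cce", "triennial_cce", "cce_triage",
                     "cce_after_fit15", "cce_after_fit47", "no_screening"):
            assert fr.status[name] != "frontier"
        icer = fr.icers["colonoscopy_10y"]
        assert abs(icer - 10_311) / 10_311 < 0.02
        assert fr.optimal == "colonoscopy_10y"

    def test_trivial_strong_dominance(self):
        fr = efficient_frontier([("a", 10.0, 100.0), ("b", 12.0, 90.0)], wtp=1000)
        assert fr.status == {"a": "strongly_dominated", "b": "frontier"}
        assert fr.optimal == "b"

    def test_extended_dominance_removed(self):
        # b lies above the segment a-c: extended dominated
        pts = [("a", 0.0, 0.0), ("b", 1.0, 100.0), ("c", 2.0, 110.0)]
        fr = efficient_frontier(pts, wtp=1_000_000)
        assert fr.status["b"] == "extended_dominated"
        assert fr.frontier == ["a", "c"]
        assert fr.icers["c"] == pytest.approx(55.0)

    def test_optimal_respects_wtp(self):
        pts = [("cheap", 0.0, 0.0), ("mid", 1.0, 50.0), ("dear", 2.0, 1_000_050.0)]
        fr = efficient_frontier(pts, wtp=100.0)
        assert fr.optimal == "mid"

    def test_frontier_icers_strictly_increase(self):
        fr = efficient_frontier(frontier_input_full_adherence(), wtp=20_000)
        icers = [fr.icers[n] for n in fr.frontier if fr.icers[n] is not None]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 1000)), min_size=2, max_size=10),
           st.permutations(range(10)))
    def test_permutation_invariance_and_monotone_icers(self, pts, perm):
        table = [(f"s{i}", q, c) for i, (q, c) in enumerate(pts)]
        fr1 = efficient_frontier(table, wtp=500.0)
        shuffled = [table[i] for i in perm if i < len(table)]
        if len(shuffled) < 2:
            return
        fr2 = efficient_frontier(shuffled, wtp=500.0)
        if len(shuffled) == len(table):
            assert set(fr1.frontier) == set(fr2.frontier)
            assert fr1.optimal == fr2.optimal
        icers = [fr1.icers[n] for n in fr1.frontier if fr1.icers[n] is not None]
        assert all(a < b for a, b in zip(icers, icers[1:]))
        assert fr1.status[fr1.optimal] == "frontier"


@pytest.fixture(scope="module")
def runs(cohort, profiles):
    base = no_screening_run(cohort)
    fit47 = run_strategy(
        cohort, STRATEGIES["biennial_fit47"], ADHERENCE_SCENARIOS["full"], profiles, seed=99
    )
    return base, fit47


class TestStrategyOutcomesAccounting:
    def test_qaly_gains_can_exceed_life_year_gains(self, runs, costs_utilities):
        """Averting high-disutility disease states adds QALYs beyond LYs."""
        costs, utils = costs_utilities
        base, fit47 = runs
        b = strategy_outcomes(base, costs, utils)
        o = strategy_outcomes(fit47, costs, utils, baseline=b)
        assert o.qaly_gained > o.ly_gained > 0

    def test_qalys_below_life_years_within_arm(self, runs, costs_utilities):
        costs, utils = costs_utilities
        base, _ = runs
        b = strategy_outcomes(base, costs, utils)
        assert b.qalys < b.life_years

    def test_rate_zero_equals_undiscounted_sums(self, runs, costs_utilities):
        costs, utils = costs_utilities
        base, fit47 = runs
        o = strategy_outcomes(fit47, costs, utils, CEAConfig(discount_rate=0.0))
        raw_fits = fit47.events.mask("fit").sum() * 1000.0 / fit47.n
        assert o.tests["fit"] == pytest.approx(raw_fits)
        out = fit47.outcomes
        assert o.life_years == pytest.approx(out.death_age.sum() * 1000.0 / fit47.n)

    def test_screening_reduces_treatment_phase_costs(self, runs, costs_utilities):
        costs, utils = costs_utilities
        base, fit47 = runs
        b = strategy_outcomes(base, costs, utils)
        o = strategy_outcomes(fit47, costs, utils)
        from capscreen.cea import COST_ITEMS

        idx = [COST_ITEMS.index(f"terminal_crc_{s}") for s in ("I", "II", "III", "IV")]
        assert o.basis.counts[idx].sum() < b.basis.counts[idx].sum()


class TestThresholdSearch:
    def test_constant_criterion_reports_no_threshold(self):
        res = threshold_search(lambda x: True, (0.0, 100.0))
        assert not res.found and res.threshold is None

    def test_flip_located_within_tolerance(self):
        res = threshold_search(lambda x: x < 61.73, (0.0, 600.0), tol=0.5)
        assert res.found
        assert abs(res.threshold - 61.73) <= 0.5

    def test_non_monotone_criterion_rejected(self):
        # true below 10, false in the middle, true again in (48, 60)
        with pytest.raises(ValueError):
            threshold_search(lambda x: x < 10.0 or 48.0 < x < 60.0, (0.0, 100.0))

    def test_invalid_bracket_rejected(self):
        with pytest.raises(ValueError):
            threshold_search(lambda x: True, (10.0, 10.0))

    def test_lower_unit_cost_never_raises_total_cost(self, cohort, profiles, costs_utilities):
        costs, utils = costs_utilities
        run = run_strategy(
            cohort, STRATEGIES["biennial_cce"], ADHERENCE_SCENARIOS["full"], profiles, seed=99
        )
        o = strategy_outcomes(run, costs, utils)
        from capscreen.cea import COST_ITEMS

        v = costs.item_values()
        full = float(o.basis.counts @ v)
        v[COST_ITEMS.index("cce")] = 300.0
        halved = float(o.basis.counts @ v)
        assert halved <= full
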