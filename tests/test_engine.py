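"""Microsimulation engine: per-cycle arithmetic, event drawing,
determinism, and agreement with an exhaustive-enumeration oracle on a
tractable toy model."""

import numpy as np
import pytest

from osteosim import engine
from osteosim.parameters import (
    Drug,
    FractureKind,
    Perspective,
    ScenarioConfig,
    Strategy,
    set_by_path,
    set_many_by_path,
)

from conftest import make_toy_params

F = FractureKind


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of the one-fracture-type,
# constant-hazard model over a short horizon


def enumerate_toy_expectation(p, q, u0, first_mult, subseq_mult, cost,
                              ncycles, rate):
    """Expected discounted (cost, qaly, fracture count) by enumerating every
    death/fracture sequence of the toy model."""

    def recurse(t, has_history, prob):
        if t == ncycles or prob == 0.0:
            return 0.0, 0.0, 0.0
        d = (1 + rate) ** (-t)
        ec = eq = ef = 0.0
        alive = prob * (1 - q)
        # no fracture this cycle
        u = u0 * (subseq_mult if has_history else 1.0)
        c1, q1, f1 = recurse(t + 1, has_history, 1.0)
        w = alive * (1 - p)
        ec += w * (0.0 + c1)
        eq += w * (u * d + q1)
        ef += w * f1
        # fracture this cycle
        w = alive * p
        c2, q2, f2 = recurse(t + 1, True, 1.0)
        ec += w * (cost * d + c2)
        eq += w * (u0 * first_mult * d + q2)
        ef += w * (1.0 + f2)
        return ec, eq, ef

    return recurse(0, False, 1.0)


def toy_scenario(ncycles, n, seed=0, rate=0.03):
    return ScenarioConfig(
        start_age=65, strategy=Strategy.NO_TREATMENT,
        horizon_end_age=65 + ncycles, discount_rate=rate,
        n_individuals=n, master_seed=seed)


class TestCycleArithmetic:
    def test_fracture_probability_is_multiplicative(self, default_ps):
        ps = set_many_by_path(default_ps, {
            "incidence.rates.hip.70": 0.01,
            "risks.rr_prior_vertebral.hip": 2.3,
            "risks.rr_osteoporosis.hip": 2.0,
        })
        p = engine.fracture_probability(70, F.HIP, ps)
        assert p == pytest.approx(0.01 * 2.3 * 2.0)
        p_treated = engine.fracture_probability(70, F.HIP, ps,
                                                treatment_rr=0.565)
        assert p_treated == pytest.approx(0.046 * 0.565)

    def test_zero_baseline_gives_zero(self, toy_params):
        assert engine.fracture_probability(70, F.HIP, toy_params) == 0.0

    def test_two_prior_hips_force_zero_probability(self, default_ps):
        assert engine.fracture_probability(
            80, F.HIP, default_ps, hip_fracture_count=2) == 0.0

    def test_age_outside_table_rejected(self, default_ps):
        with pytest.raises(ValueError):
            engine.fracture_probability(40, F.HIP, default_ps)

    def test_mortality_attributable_excess(self):
        ps = set_by_path(make_toy_params(q_death=0.04),
                         "risks.hip_excess_mortality_rr", 2.0)
        assert engine.mortality_probability(70, False, ps) == 0.04
        # only 25% of the excess RR applies: 0.04 * (1 + 0.25 * 1) = 0.05
        assert engine.mortality_probability(70, True, ps) == pytest.approx(0.05)

    def test_null_excess_rr_leaves_mortality_unchanged(self, default_ps):
        ps = set_by_path(default_ps, "risks.hip_excess_mortality_rr", 1.0)
        q = ps.mortality.q[75]
        assert engine.mortality_probability(75, True, ps) == q


class TestEventDraw:
    def test_all_zero_probabilities_never_fire(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert engine.draw_cycle_event(
                [0, 0, 0, 0], rng.random(), rng.random()) is None

    def test_certain_single_event_always_fires(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert engine.draw_cycle_event(
                [1.0, 0, 0, 0], rng.random(), rng.random()) == 0

    def test_competing_risk_frequencies(self):
        # two risks at 0.1: P(any) = 1 - 0.9^2 = 0.19, P(first | any) = 0.5
        rng = np.random.default_rng(12345)
        n = 20_000
        events = [engine.draw_cycle_event([0.1, 0.1, 0, 0],
                                          rng.random(), rng.random())
                  for _ in range(n)]
        k_any = sum(e is not None for e in events)
        se_any = np.sqrt(0.19 * 0.81 / n)
        assert abs(k_any / n - 0.19) < 3 * se_any
        k_first = sum(e == 0 for e in events)
        se_first = np.sqrt(0.25 / k_any)
        assert abs(k_first / k_any - 0.5) < 3 * se_first


class TestTrajectories:
    def test_same_seed_identical_trajectory(self, default_ps):
        sc = ScenarioConfig(start_age=65, strategy=Strategy.SEQUENTIAL,
                            n_individuals=1, master_seed=7)
        t1 = engine.simulate_individual(default_ps, sc, seed=42)
        t2 = engine.simulate_individual(default_ps, sc, seed=42)
        assert t1 == t2

    def test_certain_death_gives_single_cycle(self, default_ps):
        ps = set_many_by_path(
            default_ps,
            {f"mortality.q.{a}": 1.0 for a in range(65, 106)})
        sc = ScenarioConfig(start_age=65, strategy=Strategy.NO_TREATMENT,
                            n_individuals=1)
        traj = engine.simulate_individual(ps, sc, seed=1)
        assert traj.died
        assert len(traj.records) == 1
        assert traj.records[0].died and traj.records[0].event is None
        assert traj.qaly == 0.0 and traj.cost_formal == 0.0

    def test_no_accrual_after_death(self, toy_params):
        ps = set_many_by_path(
            toy_params, {f"mortality.q.{a}": 0.5 for a in range(65, 106)})
        sc = toy_scenario(10, 1)
        for seed in range(30):
            traj = engine.simulate_individual(ps, sc, seed=seed)
            if traj.died:
                assert traj.records[-1].died
                assert traj.records[-1].utility == 0.0
                assert not traj.records[-1].components

    def test_hip_fractures_capped_at_two(self, default_ps):
        # force huge hip incidence: every woman fractures almost every cycle
        ps = set_many_by_path(default_ps, {
            **{f"incidence.rates.hip.{a}": 0.2 for a in range(65, 106)},
            **{f"mortality.q.{a}": 0.0 for a in range(65, 105)},
            "risks.rr_prior_vertebral.hip": 1.0,
            "risks.rr_osteoporosis.hip": 1.0,
            "risks.hip_excess_mortality_rr": 1.0,
        })
        sc = ScenarioConfig(start_age=65, strategy=Strategy.NO_TREATMENT,
                            n_individuals=200, master_seed=3)
        res = engine.run_cohort(ps, sc)
        assert res.fracture_counts[:, 0].max() == 2

    def test_qalys_bounded_by_years_lived(self, default_ps):
        sc = ScenarioConfig(start_age=80, strategy=Strategy.NO_TREATMENT,
                            n_individuals=300, master_seed=5,
                            discount_rate=0.0)
        res = engine.run_cohort(default_ps, sc)
        assert (res.qaly <= (105 - 80) + 1e-9).all()

    def test_societal_cost_dominates_health_care_cost(self, default_ps):
        sc = ScenarioConfig(start_age=70, strategy=Strategy.SEQUENTIAL,
                            n_individuals=300, master_seed=11)
        res = engine.run_cohort(default_ps, sc)
        assert (res.cost_societal >= res.cost_health_care - 1e-9).all()


class TestCohortStatistics:
    def test_single_individual_cohort_equals_trajectory(self, default_ps):
        sc = ScenarioConfig(start_age=65, strategy=Strategy.SEQUENTIAL,
                            n_individuals=1, master_seed=9)
        res = engine.run_cohort(default_ps, sc)
        traj = engine.simulate_individual(
            default_ps, sc,
            seed=engine._individual_seed(9, (engine.STREAM_BASE_CASE,), 0))
        assert res.qaly[0] == pytest.approx(traj.qaly)
        assert res.cost_societal[0] == pytest.approx(
            traj.total_cost(Perspective.SOCIETAL))

    def test_survival_dead_by_105(self, default_ps):
        for start in (65, 80):
            sc = ScenarioConfig(start_age=start,
                                strategy=Strategy.NO_TREATMENT,
                                n_individuals=1500, master_seed=2)
            res = engine.run_cohort(default_ps, sc)
            assert res.fraction_dead >= 0.99

    def test_toy_mean_fracture_count_matches_binomial(self, toy_params):
        # 2 cycles, p = 0.1, no death: E[count] = 0.2
        sc = toy_scenario(2, 20_000, seed=4)
        res = engine.run_cohort(toy_params, sc)
        counts = res.fracture_counts.sum(axis=1)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 0.2) < 3 * se

    def test_enumeration_oracle_equivalence(self):
        p, q, u0, fm, sm, cost, rate = 0.1, 0.05, 0.8, 0.9, 0.95, 1000.0, 0.03
        ps = make_toy_params(p_fracture=p, q_death=q, baseline_utility=u0,
                             first_mult=fm, subseq_mult=sm,
                             fracture_cost=cost)
        ec, eq, ef = enumerate_toy_expectation(p, q, u0, fm, sm, cost, 3, rate)
        sc = toy_scenario(3, 20_000, seed=8, rate=rate)
        res = engine.run_cohort(ps, sc)
        for observed, expected in (
            (res.cost_societal, ec),
            (res.qaly, eq),
            (res.fracture_counts.sum(axis=1), ef),
        ):
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 3 * se


class TestStrategyComparisons:
    def test_null_treatment_makes_strategies_equivalent(self, default_ps):
        subs = {}
        for drug in Drug:
            for kind in F:
                subs[f"efficacy.{drug.value}.{kind.value}.rr_trial"] = 1.0
                subs[f"efficacy.{drug.value}.{kind.value}.range_high"] = 1.0
            subs[f"costs.annual_drug_cost.{drug.value}"] = 0.0
        ps = set_many_by_path(default_ps, subs)
        sc = ScenarioConfig(start_age=70, n_individuals=800, master_seed=6,
                            common_random_numbers=True)
        inter, comp = engine.run_strategy_pair(ps, sc)
        # identical hazards + common random numbers => identical event paths
        diff = inter.qaly - comp.qaly
        se = max(diff.std(ddof=1) / np.sqrt(len(diff)), 1e-12)
        assert abs(diff.mean()) < 3 * se

    def test_lower_treatment_rr_never_increases_fractures(self, default_ps):
        sc = ScenarioConfig(start_age=65, strategy=Strategy.SEQUENTIAL,
                            n_individuals=2500, master_seed=13)
        base = engine.run_cohort(default_ps, sc)
        stronger = set_many_by_path(default_ps, {
            f"efficacy.{d.value}.{k.value}.rr_trial": max(
                0.1, default_ps.efficacy[d][k].rr_trial - 0.2)
            for d in Drug for k in F
            if default_ps.efficacy[d][k].rr_trial - 0.2 >=
               default_ps.efficacy[d][k].range_low
        })
        res = engine.run_cohort(stronger, sc)
        assert (res.fracture_counts.sum(axis=1).mean()
                <= base.fracture_counts.sum(axis=1).mean() + 1e-9)
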