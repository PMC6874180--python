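"""Distribution sampling, one-way/threshold analyses, PSA, and CEAC."""

import numpy as np
import pytest

from osteosim import economics as econ
from osteosim import sensitivity as sens
from osteosim.engine import STREAM_PSA, run_strategy_pair
from osteosim.parameters import (
    DistributionSpec,
    Perspective,
    ScenarioConfig,
    get_by_path,
)

RNG_SEED = 20240917


class TestSampling:
    def test_point_mass_is_constant(self):
        spec = DistributionSpec(kind="point_mass", base=0.42, low=0.1, high=1.0)
        rng = np.random.default_rng(RNG_SEED)
        assert all(sens.sample_parameter(spec, rng) == 0.42 for _ in range(20))

    def test_triangular_mean_and_support(self):
        a, c, b = 0.10, 0.42, 1.0
        spec = DistributionSpec(kind="triangular", base=c, low=a, high=b)
        rng = np.random.default_rng(RNG_SEED)
        x = np.array([sens.sample_parameter(spec, rng) for _ in range(50_000)])
        assert x.min() >= a and x.max() <= b
        mean = (a + b + c) / 3
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - mean) < 3 * se

    def test_beta_mean_and_support(self):
        spec = DistributionSpec(kind="beta", base=0.30, low=0.16, high=0.55)
        rng = np.random.default_rng(RNG_SEED)
        x = np.array([sens.sample_parameter(spec, rng) for _ in range(50_000)])
        assert x.min() >= 0.16 and x.max() <= 0.55
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 0.30) < 3 * se

    def test_lognormal_median_matches_base(self):
        spec = DistributionSpec(kind="log_normal", base=29_986,
                                low=25_677, high=42_913)
        rng = np.random.default_rng(RNG_SEED)
        n = 50_000
        x = np.array([sens.sample_parameter(spec, rng) for _ in range(n)])
        assert (x > 0).all()
        # order-statistic check: the fraction below the median is 1/2
        frac_below = (x < 29_986).mean()
        assert abs(frac_below - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_gamma_mean_matches_base(self):
        spec = DistributionSpec(kind="gamma", base=2.3, low=2.0, high=2.8)
        rng = np.random.default_rng(RNG_SEED)
        x = np.array([sens.sample_parameter(spec, rng) for _ in range(50_000)])
        assert (x > 0).all()
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 2.3) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec(kind="beta", base=2.0, low=0.0, high=1.0)
        with pytest.raises(ValueError):
            sens.sample_parameter(
                DistributionSpec(kind="log_normal", base=0.0, low=0.0, high=1.0),
                np.random.default_rng(0))


def small_scenario(n=400, seed=1):
    return ScenarioConfig(start_age=70, n_individuals=n, master_seed=seed)


class TestOWSA:
    def test_empty_values_list(self, default_ps):
        assert sens.run_owsa(default_ps, small_scenario(),
                             "costs.dxa_cost", []) == []

    def test_base_value_reproduces_base_icer(self, default_ps):
        sc = small_scenario()
        base = sens._paired_icer(default_ps, sc)
        path = "costs.annual_drug_cost.teriparatide"
        (repeat,) = sens.run_owsa(default_ps, sc, path,
                                  [get_by_path(default_ps, path)])
        assert repeat.delta_cost == pytest.approx(base.delta_cost)
        assert repeat.delta_qaly == pytest.approx(base.delta_qaly)

    def test_icer_monotone_in_teriparatide_cost(self, default_ps):
        sc = small_scenario(n=600)
        values = [5_000.0, 12_000.0, 20_161.0, 27_618.0]
        results = sens.run_owsa(default_ps, sc,
                                "costs.annual_drug_cost.teriparatide", values)
        icers = [(r.icer if r.icer is not None else -np.inf) for r in results]
        assert icers == sorted(icers)

    def test_unknown_path_raises(self, default_ps):
        with pytest.raises(KeyError):
            sens.run_owsa(default_ps, small_scenario(), "bogus.path", [1.0])


class TestThreshold:
    def test_infinite_wtp_selects_first_grid_point(self, default_ps):
        res = sens.threshold_discount(
            default_ps, small_scenario(n=120), wtp=np.inf,
            discounts=(0.30, 0.35))
        assert res.discount == 0.30

    def test_unreachable_wtp_finds_none(self, default_ps):
        res = sens.threshold_discount(
            default_ps, small_scenario(n=120), wtp=-1e12,
            discounts=(0.30, 0.95))
        assert res.discount is None

    def test_threshold_non_increasing_in_wtp(self, default_ps):
        sc = small_scenario(n=500)
        grid = (0.30, 0.50, 0.70, 0.90)
        low = sens.threshold_discount(default_ps, sc, wtp=100_000,
                                      discounts=grid)
        high = sens.threshold_discount(default_ps, sc, wtp=500_000,
                                       discounts=grid)
        if low.discount is not None:
            assert high.discount is not None
            assert high.discount <= low.discount


class TestPSA:
    def _point_mass_params(self, ps):
        from osteosim.parameters import set_many_by_path

        pm = {
            path: DistributionSpec(kind="point_mass",
                                   base=get_by_path(ps, path),
                                   low=get_by_path(ps, path),
                                   high=get_by_path(ps, path))
            for path in ps.uncertainty
        }
        out = ps.model_copy(deep=True)
        out.uncertainty.clear()
        out.uncertainty.update(pm)
        return out

    def test_point_mass_psa_reproduces_base_case_exactly(self, default_ps):
        ps = self._point_mass_params(default_ps)
        sc = small_scenario(n=300, seed=5)
        psa = sens.run_psa(ps, sc, n_simulations=2, n_trials=300, seed=5)
        # both simulations are the base case under identical seeds
        assert psa.delta_cost[0] == psa.delta_cost[1]
        assert psa.delta_qaly[0] == psa.delta_qaly[1]
        inner = sc.model_copy(update={"n_individuals": 300, "master_seed": 5})
        inter, comp = run_strategy_pair(ps, inner, stream=(STREAM_PSA, 1))
        base_dc = (inter.mean_cost(Perspective.SOCIETAL)
                   - comp.mean_cost(Perspective.SOCIETAL))
        base_de = inter.mean_qaly - comp.mean_qaly
        assert psa.delta_cost[0] == base_dc
        assert psa.delta_qaly[0] == base_de

    def test_psa_reproducible_given_seed(self, default_ps):
        sc = small_scenario(n=100, seed=3)
        a = sens.run_psa(default_ps, sc, n_simulations=3, n_trials=100, seed=3)
        b = sens.run_psa(default_ps, sc, n_simulations=3, n_trials=100, seed=3)
        assert (a.delta_cost == b.delta_cost).all()
        assert (a.delta_qaly == b.delta_qaly).all()


class TestCEAC:
    def _hand_psa(self):
        return sens.PSAResult(
            delta_cost=np.array([100.0, -50.0, 200.0, 0.0]),
            delta_qaly=np.array([0.01, 0.002, -0.001, 0.0]),
            n_simulations=4, n_trials=10, seed=0,
            perspective=Perspective.SOCIETAL)

    def test_hand_counted_fractions(self):
        psa = self._hand_psa()
        curve = dict(sens.ceac(psa, [0.0, 150_000.0]))
        # wtp=0: count of pairs with delta_cost <= 0 -> 2/4
        assert curve[0.0] == 0.5
        # wtp=150k: NMB >= 0 for (100,.01), (-50,.002), (0,0) -> 3/4
        assert curve[150_000.0] == 0.75

    def test_wtp_zero_equals_probability_of_cost_saving(self):
        rng = np.random.default_rng(RNG_SEED)
        psa = sens.PSAResult(
            delta_cost=rng.normal(50, 100, 500),
            delta_qaly=rng.normal(0.01, 0.005, 500),
            n_simulations=500, n_trials=10, seed=0,
            perspective=Perspective.SOCIETAL)
        ((_, frac),) = sens.ceac(psa, [0.0])
        assert frac == (psa.delta_cost <= 0).mean()

    def test_monotone_when_all_qaly_gains_positive(self):
        rng = np.random.default_rng(RNG_SEED)
        psa = sens.PSAResult(
            delta_cost=rng.normal(1000, 400, 300),
            delta_qaly=np.abs(rng.normal(0.01, 0.005, 300)) + 1e-6,
            n_simulations=300, n_trials=10, seed=0,
            perspective=Perspective.SOCIETAL)
        fracs = [f for _, f in sens.ceac(psa, np.linspace(0, 5e9, 21))]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0

    def test_empty_psa_rejected(self):
        psa = self._hand_psa()
        psa.n_simulations = 0
        psa.delta_cost = np.array([])
        psa.delta_qaly = np.array([])
        with pytest.raises(ValueError):
            sens.ceac(psa, [0.0])
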