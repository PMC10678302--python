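"""Sensitivity protocol: tornado linearity and variance control,
dependence and uptake sweeps, and the Poisson pipeline extension."""

import numpy as np
import pytest

from gtbudget.engine import SimulationConfig
from gtbudget.registry import generate_registry, registry_to_csv_bytes
from gtbudget.sensitivity import (
    PipelineTrend,
    correlation_sweep,
    fit_pipeline_trend,
    pipeline_scenario,
    program_start_years,
    simulate_pipeline_entry,
    tornado,
    uptake_sweep,
)


@pytest.fixture(scope="module")
def registry():
    # several programs per disease so correlation has something to act on
    return generate_registry(6, 20, seed=33)


@pytest.fixture(scope="module")
def config():
    return SimulationConfig(n_iterations=150, seed=12)


class TestTornado:
    def test_linear_variables_shift_spending_by_exactly_the_perturbation(
        self, registry, config
    ):
        table = tornado(registry, config, variables=("price_per_qaly", "delta_qaly"))
        spending_rows = table[table.metric != "peak_month"]
        for _, row in spending_rows.iterrows():
            expected = 20.0 if row.direction == "up" else -20.0
            assert row.percent_change == pytest.approx(expected, abs=1e-9)
            assert row.peak_shift_months == 0

    def test_zero_perturbation_reproduces_baseline(self, registry, config):
        table = tornado(registry, config, variables=("theta_max", "pos_3a"),
                        perturbation=0.0)
        assert np.allclose(table.percent_change, 0.0)
        assert (table.peak_shift_months == 0).all()

    def test_slower_review_reduces_in_horizon_spending(self, registry, config):
        table = tornado(registry, config, variables=("days_bla_to_approval",))
        cum = table[(table.metric == "cumulative_spending_nominal")]
        up = float(cum[cum.direction == "up"].percent_change.iloc[0])
        down = float(cum[cum.direction == "down"].percent_change.iloc[0])
        # time perturbations move spending in the opposite direction, mildly
        assert up <= 0.0 <= down
        assert max(abs(up), abs(down)) < 20.0

    def test_unknown_variable_rejected(self, registry, config):
        with pytest.raises(ValueError):
            tornado(registry, config, variables=("not_a_variable",))


class TestCorrelationSweep:
    def test_spending_nonincreasing_in_correlation(self, registry):
        cfg = SimulationConfig(n_iterations=1500, seed=7)
        table = correlation_sweep(registry, cfg, [0.0, 0.5, 1.0])
        spend = table.cumulative_spending_discounted.to_numpy()
        assert spend[0] >= spend[1] >= spend[2]

    def test_comonotone_identical_pos_is_all_or_nothing(self):
        # one oncology program per disease and rho=1: every iteration approves
        # either every viable disease or none
        from gtbudget.approval import simulate_successes

        progs = [(f"p{i}", "Oncology") for i in range(6)]
        for seed in range(100):
            flags = simulate_successes(progs, correlation=1.0,
                                       rng=np.random.default_rng(seed))
            assert len(set(flags.values())) == 1

    def test_single_program_marginals_insensitive_to_correlation(self):
        reg = generate_registry(8, 8, seed=40)  # exactly one trial per disease
        assert reg.programs().groupby("disease_id").size().max() == 1
        cfg = SimulationConfig(n_iterations=2000, seed=3)
        table = correlation_sweep(reg, cfg, [0.0, 1.0])
        a, b = table.expected_approvals.to_numpy()
        # each disease's marginal equals its single program's PoS at any rho
        assert a == pytest.approx(b, abs=3 * np.sqrt(8 * 0.25 / 2000))


class TestUptakeSweep:
    def test_baseline_fraction_changes_nothing(self, registry, config):
        table = uptake_sweep(registry, config, [0.25])
        assert table.percent_change.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_slow_uptake_defers_spending_past_horizon(self, registry, config):
        table = uptake_sweep(registry, config, [0.05])
        assert table.percent_change.iloc[0] < 0.0

    def test_monotone_up_to_saturation_then_flat(self, registry, config):
        # spending grows with the first-year fraction below the baseline and
        # saturates near it: faster-than-baseline uptake concentrates demand
        # in the early ramp months and cannot raise spending much further
        table = uptake_sweep(registry, config, [0.05, 0.10, 0.175, 0.25, 0.50])
        spend = table.cumulative_spending_discounted.to_numpy()
        assert (np.diff(spend[:4]) >= -1e-9 * spend[0]).all()
        drop_below = abs(table.percent_change.iloc[0])      # e.g. tens of percent
        drift_above = abs(table.percent_change.iloc[-1])    # small near saturation
        assert drift_above < drop_below / 2

    def test_out_of_range_fraction_rejected(self, registry, config):
        with pytest.raises(ValueError):
            uptake_sweep(registry, config, [1.5])


class TestPipelineTrend:
    def test_exact_line_recovered(self):
        years = [2015] * 2 + [2016] * 4 + [2017] * 6
        trend = fit_pipeline_trend(years)
        assert trend.slope == pytest.approx(2.0)
        assert trend.rate(2018) == pytest.approx(8.0)

    def test_constant_counts_give_zero_slope(self):
        years = [2015] * 3 + [2016] * 3 + [2017] * 3
        trend = fit_pipeline_trend(years)
        assert trend.slope == pytest.approx(0.0, abs=1e-9)
        assert trend.rate(2030) == pytest.approx(3.0)

    def test_noisy_linear_counts_recovered_within_se(self, rng):
        slope_true, intercept0 = 1.5, 4.0
        years = []
        grid = np.arange(2005, 2020)
        noise = rng.normal(0.0, 1.0, grid.size)
        for i, y in enumerate(grid):
            count = max(0, int(round(intercept0 + slope_true * i + noise[i])))
            years += [int(y)] * count
        trend = fit_pipeline_trend(years)
        x = grid - grid.mean()
        se = 1.0 / np.sqrt(np.sum(x**2))  # OLS slope SE at unit noise
        assert abs(trend.slope - slope_true) < 3 * se + 0.15  # rounding slack

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            fit_pipeline_trend([2018, 2018])

    def test_negative_extrapolation_truncates_to_zero(self):
        trend = PipelineTrend(slope=-2.0, intercept=4000.0)
        assert trend.rate(2030) == 0.0


class TestPipelineEntry:
    def test_zero_rate_adds_nothing(self, registry, rng):
        out = simulate_pipeline_entry(PipelineTrend(0.0, 0.0), (2020, 2034), rng, registry)
        assert registry_to_csv_bytes(out) == registry_to_csv_bytes(registry)

    def test_poisson_arrival_mean(self, registry):
        trend = PipelineTrend(0.0, 12.0)  # constant 12 programs/year
        totals = []
        for seed in range(200):
            out = simulate_pipeline_entry(
                trend, (2020, 2029), np.random.default_rng(seed), registry)
            totals.append(len(out.diseases) - len(registry.diseases))
        mean = np.mean(totals)
        se = np.sqrt(120.0 / 200)  # Poisson(120) replicate SE
        assert abs(mean - 120.0) < 3 * se

    def test_zero_trend_scenario_reproduces_baseline(self, registry, config):
        base, ext = pipeline_scenario(registry, config, trend=PipelineTrend(0.0, 0.0))
        assert base.summary_metrics() == ext.summary_metrics()

    def test_extension_never_decreases_totals(self, registry, config):
        trend = fit_pipeline_trend(program_start_years(registry))
        base, ext = pipeline_scenario(registry, config, trend=trend)
        assert ext.expected_approvals >= base.expected_approvals
        assert ext.cumulative_patients >= base.cumulative_patients - 1e-9
        assert ext.cumulative_spending_nominal >= base.cumulative_spending_nominal - 1e-6
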