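"""Monte Carlo engine: closed-form single-disease checks, conservation,
homogeneity, discounting, and the payer decomposition."""

import numpy as np
import pytest

from gtbudget.engine import (
    SimulationConfig,
    discount,
    payer_decomposition,
    run_monte_carlo,
    tax_share_percent,
)
from gtbudget.pricing import PriceModel
from gtbudget.registry import generate_registry

from conftest import make_single_disease_registry

NO_LAGS = {"days_p3_to_bla": 0.0, "days_bla_to_approval": 0.0}


def _plateau_config(**kw):
    base = dict(
        n_iterations=1,
        seed=0,
        ramp_dispersion=0.0,
        price_model=PriceModel(price_per_qaly_rare=100_000.0),
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestClosedFormSingleDisease:
    """A dispersionless prior-approval rare disease admits hand computation:
    approval December 2020, ramp to 40% over 6 months, 10 new patients/month,
    price = 10 QALYs x $100k = $1M."""

    def test_spending_plateau_matches_hand_arithmetic(self):
        reg = make_single_disease_registry(
            incidence_i=120.0, prevalence_j=0.0, delta_qaly=10.0, prior_approval=True
        )
        res = run_monte_carlo(reg, _plateau_config())
        mean = res.spending["total"].mean
        # approval month 11 (Dec 2020): rho(0)=0, spending starts Jan 2021
        assert mean[:12].sum() == 0.0
        assert mean[12] > 0.0
        # plateau from 6 months after approval: 0.4 * 10/mo * $1M = $4M/mo
        assert np.allclose(mean[17:], 4e6, rtol=1e-12)
        # ramp midpoint, 3 months in: half the plateau
        assert mean[14] == pytest.approx(2e6, rel=1e-12)

    def test_patients_and_qalys_consistent_with_spending(self):
        reg = make_single_disease_registry(delta_qaly=10.0)
        res = run_monte_carlo(reg, _plateau_config())
        assert np.allclose(res.patients["total"].mean[17:], 4.0, rtol=1e-12)
        assert res.qalys_cumulative.mean[-1] == pytest.approx(
            res.patients["total"].mean.sum() * 10.0, rel=1e-9
        )

    def test_all_failed_pipeline_gives_zero_series(self):
        reg = make_single_disease_registry(prior_approval=False)
        cfg = _plateau_config(pos_table={a: 0.0 for a in (
            "Autoimmune/Inflammation", "Cardiovascular", "CNS",
            "Metabolic/Endocrinology", "Oncology", "Ophthalmology")})
        res = run_monte_carlo(reg, cfg)
        assert res.spending["total"].mean.sum() == 0.0
        assert res.expected_approvals == 0.0


class TestMonteCarloContracts:
    def test_single_iteration_bands_collapse_onto_mean(self, small_registry):
        res = run_monte_carlo(small_registry, SimulationConfig(n_iterations=1, seed=3))
        for band in (res.spending["total"], res.patients["total"], res.approvals_cumulative):
            assert np.allclose(band.lower, band.mean)
            assert np.allclose(band.upper, band.mean)

    def test_deterministic_pipeline_has_zero_width_bands(self):
        reg = generate_registry(6, 12, seed=5, missing_end_date_fraction=0.0)
        cfg = SimulationConfig(
            n_iterations=40, seed=0, ramp_dispersion=0.0,
            pos_table={a: 1.0 for a in (
                "Autoimmune/Inflammation", "Cardiovascular", "CNS",
                "Metabolic/Endocrinology", "Oncology", "Ophthalmology")},
            scales=dict(NO_LAGS),
        )
        res = run_monte_carlo(reg, cfg)
        assert np.allclose(res.spending["total"].lower, res.spending["total"].upper)
        assert res.spending["total"].mean.sum() > 0

    def test_same_seed_reproducible(self, small_registry):
        cfg = SimulationConfig(n_iterations=30, seed=17)
        a = run_monte_carlo(small_registry, cfg)
        b = run_monte_carlo(small_registry, cfg)
        assert np.array_equal(a.spending["total"].mean, b.spending["total"].mean)
        assert a.payer == b.payer

    def test_streams_and_categories_conserve_totals(self, small_registry):
        res = run_monte_carlo(small_registry, SimulationConfig(n_iterations=50, seed=2))
        for table in (res.patients, res.spending):
            total = table["total"].mean
            np.testing.assert_allclose(table["new"].mean + table["existing"].mean,
                                       total, rtol=1e-9)
            np.testing.assert_allclose(
                table["cancer"].mean + table["rare"].mean + table["general"].mean,
                total, rtol=1e-9)
        assert sum(res.payer.values()) == pytest.approx(
            res.average_annual_spending, rel=1e-9)

    def test_spending_linear_in_price_patients_invariant(self, small_registry):
        cfg = SimulationConfig(n_iterations=40, seed=9)
        base = run_monte_carlo(small_registry, cfg)
        doubled = run_monte_carlo(
            small_registry, cfg.replace(price_model=cfg.price_model.scaled(2.0)))
        np.testing.assert_allclose(
            doubled.spending["total"].mean, 2.0 * base.spending["total"].mean, rtol=1e-9)
        np.testing.assert_allclose(
            doubled.patients["total"].mean, base.patients["total"].mean, rtol=1e-12)

    def test_doubling_qaly_doubles_spending_not_patients(self, small_registry):
        cfg = SimulationConfig(n_iterations=40, seed=9)
        base = run_monte_carlo(small_registry, cfg)
        reg2 = small_registry.copy()
        for d in reg2.diseases:
            d.delta_qaly *= 2.0
        doubled = run_monte_carlo(reg2, cfg)
        np.testing.assert_allclose(
            doubled.spending["total"].mean, 2.0 * base.spending["total"].mean, rtol=1e-9)
        np.testing.assert_allclose(
            doubled.patients["total"].mean, base.patients["total"].mean, rtol=1e-12)

    def test_analytic_expected_approvals_at_zero_correlation(self):
        # with rho=0 the expected approval count is sum_d 1 - prod_p (1 - PoS_p)
        from gtbudget.approval import DEFAULT_POS_TABLE

        reg = generate_registry(10, 30, seed=21, missing_end_date_fraction=0.0)
        cfg = SimulationConfig(n_iterations=4000, seed=4, correlation=0.0)
        res = run_monte_carlo(reg, cfg)

        programs = reg.programs()
        expected, variance = 0.0, 0.0
        for d in reg.diseases:
            if d.prior_approval:
                expected += 1.0
                continue
            last_end = max(t.end_date for t in reg.trials_for(d.disease_id))
            if last_end < __import__("datetime").date(2017, 1, 1):
                continue
            fail = 1.0
            for _, row in programs[programs.disease_id == d.disease_id].iterrows():
                fail *= 1.0 - DEFAULT_POS_TABLE[row.therapeutic_area]
            p = 1.0 - fail
            expected += p
            variance += p * (1.0 - p)
        se = np.sqrt(variance / cfg.n_iterations)
        assert abs(res.expected_approvals - expected) < 3 * se + 1e-9


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        s = np.arange(12.0)
        np.testing.assert_array_equal(discount(s, 0.0), s)

    def test_constant_dollar_geometric_sum(self):
        pv = discount(np.ones(12), 0.03).sum()
        expected = sum(1.03 ** (-m / 12.0) for m in range(12))
        assert pv == pytest.approx(expected, rel=1e-12)

    def test_discounted_never_exceeds_nominal(self, small_registry):
        res = run_monte_carlo(small_registry, SimulationConfig(n_iterations=20, seed=1))
        assert res.cumulative_spending_discounted <= res.cumulative_spending_nominal

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount(np.ones(3), -0.01)


class TestPayerDecomposition:
    def test_all_elderly_goes_to_medicare(self):
        out = payer_decomposition({"minor": 0.0, "adult": 0.0, "elderly": 1.0}, total=1e9)
        assert out == {"Medicare": 1e9, "Medicaid": 0.0, "private": 0.0}

    def test_two_in_five_minors_on_medicaid(self):
        out = payer_decomposition({"minor": 1.0, "adult": 0.0, "elderly": 0.0}, total=1e9)
        assert out["Medicaid"] == pytest.approx(0.4e9)
        assert out["private"] == pytest.approx(0.6e9)
        assert out["Medicare"] == 0.0

    def test_published_age_shares_decompose_consistently(self):
        total = 20.4e9
        out = payer_decomposition(
            {"minor": 0.432, "adult": 0.260, "elderly": 0.309}, total=total)
        assert sum(out.values()) == pytest.approx(total, rel=1e-9)
        assert out["Medicare"] / total == pytest.approx(0.309, abs=1e-3)

    def test_bad_shares_rejected(self):
        with pytest.raises(ValueError):
            payer_decomposition({"minor": 0.7, "adult": 0.7, "elderly": 0.1}, total=1.0)
        with pytest.raises(ValueError):
            payer_decomposition({"minor": 1.0, "adult": 1.0})


class TestScalarHelpers:
    def test_tax_share_of_published_aggregates(self):
        assert tax_share_percent(20.4e9, 3.33e12) == pytest.approx(0.612, abs=1e-3)

    def test_monthly_frame_is_tidy(self, small_registry):
        res = run_monte_carlo(small_registry, SimulationConfig(n_iterations=5, seed=0))
        frame = res.monthly_frame()
        assert set(frame.columns) == {"month", "metric", "split", "mean", "lower", "upper"}
        assert (frame.groupby(["metric", "split"]).size() == 180).all()
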