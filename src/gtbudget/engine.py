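"""Monte Carlo driver.

Each iteration draws one future of the pipeline: correlated program
successes, imputed trial end dates, regulatory lags, and penetration ramps;
approved diseases then contribute monthly treated patients (new inflow plus
depleting pre-approval stock), spending (patients times the QALY-anchored
price), and QALYs gained.  Iterations are reduced to elementwise means and
pointwise percentile bands over the simulation horizon (default January
2020 – December 2034), with annual spending totals and a payer
decomposition of spending by age group (elderly → Medicare; two in five
minors and one in seven adults → Medicaid; remainder private).

Per-iteration random streams are derived from the master seed with spawn
keys, so results are independent of batch order, and perturbed reruns that
share a seed (tornado analysis) reuse the same draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import epi
from .approval import (
    DEFAULT_POS_TABLE,
    TimingModel,
    disease_approval,
    fit_duration_gamma,
    impute_end_dates,
    simulate_successes,
)
from .pricing import DEFAULT_PRICE_MODEL, PriceModel
from .registry import AGE_GROUPS, CATEGORIES, Registry, adjust_overlaps

__all__ = [
    "SimulationConfig",
    "SeriesBand",
    "SimulationResult",
    "run_iteration",
    "run_monte_carlo",
    "discount",
    "payer_decomposition",
    "tax_share_percent",
]

#: Variables that may be perturbed multiplicatively via ``SimulationConfig.scales``.
PERTURBABLE = (
    "theta_max", "t_max", "delta_qaly", "price_per_qaly", "pos_3a",
    "new_patients", "existing_patients", "days_p3_to_bla", "days_bla_to_approval",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulation study.

    ``horizon_months=180`` spans January 2020 through December 2034.
    ``n_iterations`` defaults to a desk-scale 10,000 (increase for
    production bands).  ``scales`` holds multiplicative perturbations for
    sensitivity analysis, keyed by the names in ``PERTURBABLE``.
    """

    horizon_months: int = 180
    n_iterations: int = 10_000
    seed: int = 0
    correlation: float = 0.9
    discount_rate_annual: float = 0.03
    first_year_fraction: float = 0.25
    ramp_dispersion: float = 0.10
    percentiles: tuple[float, float] = (5.0, 95.0)
    pos_table: dict | None = None
    price_model: PriceModel = DEFAULT_PRICE_MODEL
    scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 <= self.correlation <= 1.0):
            raise ValueError("correlation must lie in [0, 1]")
        if self.discount_rate_annual < 0:
            raise ValueError("discount rate must be >= 0")
        unknown = set(self.scales) - set(PERTURBABLE)
        if unknown:
            raise ValueError(f"unknown perturbation variables: {sorted(unknown)}")

    def scale(self, name: str) -> float:
        return float(self.scales.get(name, 1.0))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SeriesBand:
    """Mean and pointwise lower/upper percentile bands of a monthly series."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    unit: str = ""


@dataclass
class IterationResult:
    """Raw monthly series for a single simulated future."""

    approvals_cum: np.ndarray                      # cumulative approvals
    patients: dict[tuple[str, str], np.ndarray]    # (category, stream) -> persons/month
    spending: dict[tuple[str, str], np.ndarray]    # (category, stream) -> USD/month
    qalys: np.ndarray                              # QALYs gained per month
    spending_by_age: dict[str, np.ndarray]         # age group -> USD/month

    def total_patients(self) -> np.ndarray:
        return sum(self.patients.values())

    def total_spending(self) -> np.ndarray:
        return sum(self.spending.values())


def _effective_epidemiology(d, scales) -> tuple[float, float]:
    """(annual incidence, existing stock), filling the missing one from the
    steady-state conversion and applying sensitivity scales."""
    inc, prev = d.incidence_i, d.prevalence_j
    if inc is None:
        inc = epi.steady_state_incidence(prev, d.survival_p, d.survival_k)
    if prev is None:
        prev = epi.steady_state_prevalence(inc, d.survival_p, d.survival_k)
    return inc * scales.get("new_patients", 1.0), prev * scales.get("existing_patients", 1.0)


def run_iteration(
    registry: Registry,
    config: SimulationConfig,
    rng: np.random.Generator,
    gamma: tuple[float, float] | None = None,
) -> IterationResult:
    """Simulate one future of the pipeline.

    The registry should be overlap-adjusted; missing trial end dates are
    imputed here using ``gamma`` (fit it once with ``fit_duration_gamma``).
    """
    H = config.horizon_months
    scales = config.scales
    reg = registry
    if any(t.end_date is None for t in reg.trials):
        if gamma is None:
            gamma = fit_duration_gamma(reg.trials)
        reg = impute_end_dates(reg, gamma, rng)

    flags = simulate_successes(
        reg.programs(),
        pos_table=config.pos_table or DEFAULT_POS_TABLE,
        correlation=config.correlation,
        rng=rng,
        pos_scale=config.scale("pos_3a"),
    )
    timing = TimingModel(
        lag_scale_bla=config.scale("days_p3_to_bla"),
        lag_scale_review=config.scale("days_bla_to_approval"),
    )
    outcomes = disease_approval(reg, flags, timing, rng)
    uptake = epi.UptakeParams.from_first_year_fraction(config.first_year_fraction)

    t_grid = np.arange(H, dtype=float)
    approvals_cum = np.zeros(H)
    patients = {(c, s): np.zeros(H) for c in CATEGORIES for s in ("new", "existing")}
    spending = {k: np.zeros(H) for k in patients}
    qalys = np.zeros(H)
    spending_by_age = {g: np.zeros(H) for g in AGE_GROUPS}

    for d in reg.diseases:
        # ramps are drawn for every disease, approved or not, so the random
        # stream stays aligned across perturbed reruns sharing a seed
        ramp = epi.draw_ramp_params(d.category, rng, config.ramp_dispersion)
        out = outcomes[d.disease_id]
        if not out.approved or out.approval_month is None or out.approval_month >= H:
            continue
        theta = min(ramp.theta_max * config.scale("theta_max"), 1.0)
        t_max = ramp.t_max * config.scale("t_max")
        m0 = out.approval_month
        approvals_cum[m0:] += 1.0

        inc_annual, existing0 = _effective_epidemiology(d, scales)
        tau = t_grid[m0:] - m0
        rho = epi.penetration(tau, theta, t_max)
        frac = epi.existing_fraction(tau, 1.0, uptake.half_life_lambda)
        p_new = rho * d.eligible_fraction * (inc_annual / 12.0)
        p_exist = rho * d.eligible_fraction * frac * existing0

        dq = d.delta_qaly * scales.get("delta_qaly", 1.0)
        price = config.price_model.rate_for(d.category) * dq * scales.get("price_per_qaly", 1.0)
        patients[(d.category, "new")][m0:] += p_new
        patients[(d.category, "existing")][m0:] += p_exist
        s_new, s_exist = p_new * price, p_exist * price
        spending[(d.category, "new")][m0:] += s_new
        spending[(d.category, "existing")][m0:] += s_exist
        qalys[m0:] += (p_new + p_exist) * dq
        disease_spend = s_new + s_exist
        for g in AGE_GROUPS:
            spending_by_age[g][m0:] += d.age_mix[g] * disease_spend

    return IterationResult(approvals_cum, patients, spending, qalys, spending_by_age)


@dataclass
class SimulationResult:
    """Reduced Monte Carlo output.

    ``patients`` and ``spending`` are keyed by split: "total", "new",
    "existing", and each category name.  ``annual_spending`` is a per-year
    table of mean and band totals; ``payer`` allocates average annual
    spending to Medicare/Medicaid/private via age shares.
    """

    config: SimulationConfig
    months: pd.PeriodIndex
    approvals_cumulative: SeriesBand
    patients: dict[str, SeriesBand]
    spending: dict[str, SeriesBand]
    qalys_cumulative: SeriesBand
    annual_spending: pd.DataFrame
    payer: dict[str, float]
    age_spending_shares: dict[str, float]

    # headline scalar metrics -------------------------------------------------
    @property
    def expected_approvals(self) -> float:
        return float(self.approvals_cumulative.mean[-1])

    @property
    def cumulative_patients(self) -> float:
        return float(self.patients["total"].mean.sum())

    @property
    def peak_month(self) -> int:
        """Index of the month with the highest mean total spending (ties
        break toward the earlier month)."""
        return int(np.argmax(self.spending["total"].mean))

    @property
    def peak_monthly_spending(self) -> float:
        return float(self.spending["total"].mean[self.peak_month])

    @property
    def cumulative_spending_nominal(self) -> float:
        return float(self.spending["total"].mean.sum())

    @property
    def cumulative_spending_discounted(self) -> float:
        return float(
            discount(self.spending["total"].mean, self.config.discount_rate_annual).sum()
        )

    @property
    def average_annual_spending(self) -> float:
        return self.cumulative_spending_nominal / (self.config.horizon_months / 12.0)

    @property
    def cumulative_qalys(self) -> float:
        return float(self.qalys_cumulative.mean[-1])

    @property
    def cost_per_qaly(self) -> float:
        q = self.cumulative_qalys
        return float("nan") if q == 0 else self.cumulative_spending_nominal / q

    def summary_metrics(self) -> dict[str, float]:
        return {
            "expected_approvals": self.expected_approvals,
            "cumulative_patients": self.cumulative_patients,
            "peak_monthly_spending": self.peak_monthly_spending,
            "peak_month": float(self.peak_month),
            "cumulative_spending_nominal": self.cumulative_spending_nominal,
            "cumulative_spending_discounted": self.cumulative_spending_discounted,
            "average_annual_spending": self.average_annual_spending,
            "cumulative_qalys": self.cumulative_qalys,
            "cost_per_qaly": self.cost_per_qaly,
        }

    def monthly_frame(self) -> pd.DataFrame:
        """Tidy table: month, metric, split, mean, lower, upper."""
        rows = []

        def emit(metric: str, split: str, band: SeriesBand) -> None:
            for m, mu, lo, hi in zip(self.months, band.mean, band.lower, band.upper):
                rows.append((str(m), metric, split, mu, lo, hi))

        emit("approvals_cumulative", "total", self.approvals_cumulative)
        for split, band in self.patients.items():
            emit("patients", split, band)
        for split, band in self.spending.items():
            emit("spending", split, band)
        emit("qalys_cumulative", "total", self.qalys_cumulative)
        return pd.DataFrame(rows, columns=["month", "metric", "split", "mean", "lower", "upper"])


def _band(draws: np.ndarray, percentiles: tuple[float, float], unit: str) -> SeriesBand:
    lo, hi = np.percentile(draws, percentiles, axis=0)
    return SeriesBand(draws.mean(axis=0), lo, hi, unit)


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Deterministic per-iteration substream, independent of batching."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(iteration,)))


def run_monte_carlo(registry: Registry, config: SimulationConfig) -> SimulationResult:
    """Run ``config.n_iterations`` independent futures and reduce them."""
    reg = adjust_overlaps(registry)
    gamma = None
    if any(t.end_date is None for t in reg.trials):
        gamma = fit_duration_gamma(reg.trials)

    H, n = config.horizon_months, config.n_iterations
    splits = ["total", "new", "existing", *CATEGORIES]
    approvals = np.empty((n, H))
    patients = {s: np.zeros((n, H)) for s in splits}
    spending = {s: np.zeros((n, H)) for s in splits}
    qalys_cum = np.empty((n, H))
    age_spend = {g: np.zeros((n, H)) for g in AGE_GROUPS}

    for i in range(n):
        it = run_iteration(reg, config, iteration_rng(config.seed, i), gamma)
        approvals[i] = it.approvals_cum
        qalys_cum[i] = np.cumsum(it.qalys)
        for (cat, stream), series in it.patients.items():
            patients["total"][i] += series
            patients[stream][i] += series
            patients[cat][i] += series
        for (cat, stream), series in it.spending.items():
            spending["total"][i] += series
            spending[stream][i] += series
            spending[cat][i] += series
        for g in AGE_GROUPS:
            age_spend[g][i] = it.spending_by_age[g]

    months = pd.period_range("2020-01", periods=H, freq="M")
    pct = config.percentiles
    n_years = H / 12.0

    # annual totals of mean/bands over per-iteration annual sums
    year_of_month = months.year
    years = sorted(set(year_of_month))
    annual_draws = np.stack(
        [spending["total"][:, year_of_month == y].sum(axis=1) for y in years], axis=1
    )
    lo, hi = np.percentile(annual_draws, pct, axis=0)
    annual = pd.DataFrame({
        "year": years,
        "mean": annual_draws.mean(axis=0),
        "lower": lo,
        "upper": hi,
    })

    age_totals = {g: float(age_spend[g].mean(axis=0).sum()) for g in AGE_GROUPS}
    grand = sum(age_totals.values())
    shares = {g: (age_totals[g] / grand if grand > 0 else 0.0) for g in AGE_GROUPS}
    payer = payer_decomposition({g: age_totals[g] / n_years for g in AGE_GROUPS})

    return SimulationResult(
        config=config,
        months=months,
        approvals_cumulative=_band(approvals, pct, "count"),
        patients={s: _band(patients[s], pct, "persons") for s in splits},
        spending={s: _band(spending[s], pct, "USD") for s in splits},
        qalys_cumulative=_band(qalys_cum, pct, "QALYs"),
        annual_spending=annual,
        payer=payer,
        age_spending_shares=shares,
    )


def discount(series, annual_rate: float, reference_month: int = 0):
    """Discount a monthly series to present value at ``reference_month``
    (month 0 = January 2020), compounding monthly at the annual rate."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    values = np.asarray(series, dtype=float)
    m = np.arange(values.shape[-1], dtype=float) - reference_month
    return values * (1.0 + annual_rate) ** (-m / 12.0)


def payer_decomposition(
    annual_spending_by_age: dict[str, float], total: float | None = None
) -> dict[str, float]:
    """Allocate annual spending by age group to payers.

    All elderly spending goes to Medicare; Medicaid covers two in five
    minors and one in seven adults; the remainder is private insurance.
    If ``total`` is given, the dict values are interpreted as age *shares*
    (which must sum to 1) of that total.
    """
    missing = set(AGE_GROUPS) - set(annual_spending_by_age)
    if missing:
        raise ValueError(f"missing age groups: {sorted(missing)}")
    minor = annual_spending_by_age["minor"]
    adult = annual_spending_by_age["adult"]
    elderly = annual_spending_by_age["elderly"]
    if min(minor, adult, elderly) < 0:
        raise ValueError("spending must be nonnegative")
    if total is not None:
        s = minor + adult + elderly
        # printed shares are typically rounded; accept small round-off and
        # renormalise so the components sum exactly to the total
        if abs(s - 1.0) > 0.01:
            raise ValueError("age shares must sum to 1")
        minor, adult, elderly = (x / s * total for x in (minor, adult, elderly))
    total = minor + adult + elderly
    medicare = elderly
    medicaid = 0.4 * minor + adult / 7.0
    return {
        "Medicare": medicare,
        "Medicaid": medicaid,
        "private": total - medicare - medicaid,
    }


def tax_share_percent(annual_spending: float, tax_revenue: float) -> float:
    """Annual spending as a percentage of aggregate tax revenue."""
    if tax_revenue <= 0:
        raise ValueError("tax_revenue must be positive")
    return 100.0 * annual_spending / tax_revenue
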