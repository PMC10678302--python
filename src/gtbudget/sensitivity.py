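"""Sensitivity protocol: tornado analysis, correlation and uptake sweeps,
and the Poisson pipeline-extension scenario.

All reruns share the baseline's random seed, so perturbed results reuse the
same underlying draws and reported deltas are not confounded by Monte Carlo
noise.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import PERTURBABLE, SimulationConfig, SimulationResult, run_monte_carlo
from .registry import Registry, TrialRecord

__all__ = [
    "TORNADO_VARIABLES",
    "PipelineTrend",
    "tornado",
    "correlation_sweep",
    "uptake_sweep",
    "fit_pipeline_trend",
    "simulate_pipeline_entry",
    "pipeline_scenario",
]

#: The nine one-at-a-time tornado variables.
TORNADO_VARIABLES = PERTURBABLE

_METRICS = (
    "peak_monthly_spending",
    "cumulative_spending_nominal",
    "cumulative_spending_discounted",
)


def tornado(
    registry: Registry,
    config: SimulationConfig,
    variables: tuple[str, ...] = TORNADO_VARIABLES,
    perturbation: float = 0.20,
) -> pd.DataFrame:
    """One-at-a-time ±perturbation analysis over the nine model variables.

    Returns a tidy table (variable, direction, metric, percent_change,
    peak_shift_months); percent changes are relative to the shared-seed
    baseline.
    """
    unknown = set(variables) - set(PERTURBABLE)
    if unknown:
        raise ValueError(f"unknown tornado variables: {sorted(unknown)}")
    base = run_monte_carlo(registry, config)
    base_metrics = {m: getattr(base, m) for m in _METRICS}
    base_peak = base.peak_month
    rows = []
    for var in variables:
        for direction, factor in (("up", 1.0 + perturbation), ("down", 1.0 - perturbation)):
            cfg = config.replace(scales={**config.scales, var: factor})
            res = run_monte_carlo(registry, cfg)
            for metric in _METRICS:
                b = base_metrics[metric]
                change = float("nan") if b == 0 else 100.0 * (getattr(res, metric) - b) / b
                rows.append((var, direction, metric, change, res.peak_month - base_peak))
    return pd.DataFrame(
        rows,
        columns=["variable", "direction", "metric", "percent_change", "peak_shift_months"],
    )


def correlation_sweep(
    registry: Registry, config: SimulationConfig, rho_values
) -> pd.DataFrame:
    """Mean discounted cumulative spending as the inter-program success
    correlation varies (shared seeds across the grid)."""
    rows = []
    for rho in rho_values:
        res = run_monte_carlo(registry, config.replace(correlation=float(rho)))
        rows.append((float(rho), res.cumulative_spending_discounted,
                     res.cumulative_spending_nominal, res.expected_approvals))
    return pd.DataFrame(
        rows,
        columns=["correlation", "cumulative_spending_discounted",
                 "cumulative_spending_nominal", "expected_approvals"],
    )


def uptake_sweep(
    registry: Registry, config: SimulationConfig, first_year_fractions,
    baseline_fraction: float = 0.25,
) -> pd.DataFrame:
    """Spending as the first-year uptake fraction of existing patients
    varies; the depletion half-life is recomputed from each fraction and
    changes are reported relative to the baseline fraction."""
    base = run_monte_carlo(
        registry, config.replace(first_year_fraction=baseline_fraction)
    ).cumulative_spending_discounted
    rows = []
    for f in first_year_fractions:
        f = float(f)
        if not (0.0 < f < 1.0):
            raise ValueError("first-year fractions must lie in (0, 1)")
        res = run_monte_carlo(registry, config.replace(first_year_fraction=f))
        v = res.cumulative_spending_discounted
        change = float("nan") if base == 0 else 100.0 * (v - base) / base
        rows.append((f, v, change))
    return pd.DataFrame(
        rows,
        columns=["first_year_fraction", "cumulative_spending_discounted", "percent_change"],
    )


@dataclass(frozen=True)
class PipelineTrend:
    """Linear trend of development-program starts per year.

    ``rate(year)`` is the extrapolated annual arrival rate kappa, truncated
    at zero."""

    slope: float
    intercept: float

    def rate(self, year: float) -> float:
        return max(0.0, self.slope * year + self.intercept)


def fit_pipeline_trend(program_start_years) -> PipelineTrend:
    """Ordinary-least-squares line through (year, number of programs started)."""
    years = np.asarray(program_start_years, dtype=float)
    if np.unique(years).size < 2:
        raise ValueError("need program starts in at least 2 distinct years")
    lo, hi = int(years.min()), int(years.max())
    grid = np.arange(lo, hi + 1, dtype=float)
    counts = np.array([(years.astype(int) == int(y)).sum() for y in grid], dtype=float)
    slope, intercept = np.polyfit(grid, counts, 1)
    return PipelineTrend(float(slope), float(intercept))


def program_start_years(registry: Registry) -> list[int]:
    """Year of each development program's first trial start."""
    firsts: dict[str, _dt.date] = {}
    for t in registry.trials:
        cur = firsts.get(t.program_id)
        if cur is None or t.start_date < cur:
            firsts[t.program_id] = t.start_date
    return [d.year for d in firsts.values()]


def simulate_pipeline_entry(
    trend: PipelineTrend,
    horizon_years: tuple[int, int],
    rng: np.random.Generator,
    registry: Registry,
) -> Registry:
    """Simulate future program arrivals as a Poisson process and attach
    them to the registry as synthetic diseases.

    Within each year, inter-arrival times are exponential with that year's
    extrapolated rate kappa (density kappa*exp(-kappa*t)); each arrival is
    assigned a disease profile (category, epidemiology, QALY gain, ages)
    drawn from the baseline registry's empirical distribution, and a single
    phase-3 trial with a missing end date so the standard imputation,
    success and spending machinery applies.  Returns a new registry of
    baseline plus arrivals.
    """
    y0, y1 = horizon_years
    templates = [d for d in registry.diseases if d.parent_disease_id is None]
    out = registry.copy()
    k = 0
    for year in range(y0, y1 + 1):
        kappa = trend.rate(year)
        if kappa <= 0:
            continue
        t = 0.0
        while True:
            t += rng.exponential(1.0 / kappa)
            if t >= 1.0:
                break
            src = templates[int(rng.integers(len(templates)))]
            did = f"PX{k:04d}"
            d = dataclasses.replace(
                src,
                disease_id=did,
                name=f"Pipeline entrant {k}",
                prior_approval=False,
                parent_disease_id=None,
                age_mix=dict(src.age_mix),
            )
            out.diseases.append(d)
            start = _dt.date(year, 1, 1) + _dt.timedelta(days=int(t * 365))
            out.trials.append(TrialRecord(
                trial_id=f"PXT{k:04d}", disease_id=did, program_id=f"{did}-P0",
                phase="3", start_date=start, end_date=None,
            ))
            k += 1
    out.validate()
    return out


def pipeline_scenario(
    registry: Registry,
    config: SimulationConfig,
    trend: PipelineTrend | None = None,
    horizon_years: tuple[int, int] = (2020, 2034),
) -> tuple[SimulationResult, SimulationResult]:
    """Baseline vs pipeline-extended simulation (shared seeds).

    The trend defaults to an OLS fit of the registry's own program starts.
    Returns (baseline_result, extended_result).
    """
    if trend is None:
        trend = fit_pipeline_trend(program_start_years(registry))
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xE47,))
    )
    extended = simulate_pipeline_entry(trend, horizon_years, rng, registry)
    return run_monte_carlo(registry, config), run_monte_carlo(extended, config)
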