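"""Epidemiological and uptake mathematics.

Four pieces of machinery link a disease's epidemiology to the number of
patients treated each month after a launch:

* steady-state conversion between incidence (new patients/year) and
  prevalence (standing stock), given k-year survival p:
  ``j = k*i / (1 - p)``;
* exponential depletion of the pre-approval patient stock with a fixed
  half-life (patients who were already diagnosed seek the new therapy at
  an exponentially decaying rate);
* a ramp ("hockey-stick") penetration curve rising linearly to a plateau
  theta_max over t_max months, the standard industry adoption model;
* the treated-patient identity combining the three:
  ``patients_t = rho(t) * [new_t + E(t, delta, lambda) * existing_0]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UptakeParams",
    "RampParams",
    "RAMP_MEANS",
    "steady_state_prevalence",
    "steady_state_incidence",
    "existing_fraction",
    "half_life_from_first_year",
    "penetration",
    "draw_ramp_params",
    "patients_treated",
]

LN2 = math.log(2.0)

#: Category-specific ramp means: (mu_theta, mu_T months).  Rare diseases
#: penetrate fast and deep (40% in 6 months); general/chronic diseases slowly
#: and shallowly (1% over 5 years); cancers sit in between (10% in 12 months).
RAMP_MEANS: dict[str, tuple[float, float]] = {
    "rare": (0.40, 6.0),
    "general": (0.01, 60.0),
    "cancer": (0.10, 12.0),
}


@dataclass(frozen=True)
class UptakeParams:
    """Existing-stock depletion parameters.

    ``half_life_lambda`` (months) and ``first_year_fraction`` are two
    parameterisations of the same assumption and must agree:
    ``first_year_fraction = 1 - 2**(-12/half_life_lambda)``.
    """

    half_life_lambda: float = 28.91
    first_year_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.half_life_lambda <= 0:
            raise ValueError("half_life_lambda must be > 0")
        implied = 1.0 - 2.0 ** (-12.0 / self.half_life_lambda)
        if abs(implied - self.first_year_fraction) > 1e-3:
            raise ValueError(
                f"inconsistent uptake params: half-life {self.half_life_lambda} "
                f"implies first-year fraction {implied:.4f}, "
                f"got {self.first_year_fraction}"
            )

    @classmethod
    def from_first_year_fraction(cls, fraction: float) -> "UptakeParams":
        lam = half_life_from_first_year(fraction)
        return cls(half_life_lambda=lam, first_year_fraction=fraction)


@dataclass(frozen=True)
class RampParams:
    """A realised penetration ramp: plateau ``theta_max`` reached at
    ``t_max`` months."""

    theta_max: float
    t_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_max <= 1.0):
            raise ValueError("theta_max must lie in [0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")


def steady_state_prevalence(incidence_i: float, survival_p: float, survival_k: float) -> float:
    """Prevalence implied by incidence at demographic steady state.

    With i new patients/year and fraction p alive after k years, the stock
    j satisfies k*i inflow = j*(1-p) outflow over k years, so j = k*i/(1-p).
    """
    _check_survival(survival_p, survival_k)
    if incidence_i < 0:
        raise ValueError("incidence must be >= 0")
    return survival_k * incidence_i / (1.0 - survival_p)


def steady_state_incidence(prevalence_j: float, survival_p: float, survival_k: float) -> float:
    """Incidence implied by prevalence at steady state: i = j*(1-p)/k."""
    _check_survival(survival_p, survival_k)
    if prevalence_j < 0:
        raise ValueError("prevalence must be >= 0")
    return prevalence_j * (1.0 - survival_p) / survival_k


def _check_survival(p: float, k: float) -> None:
    if not (0.0 <= p < 1.0):
        raise ValueError("survival_p must lie in [0, 1); an immortal cohort has no steady state")
    if k <= 0:
        raise ValueError("survival_k must be > 0")


def existing_fraction(t_months, delta_months: float, half_life_lambda: float):
    """Fraction of the pre-approval patient stock seeking treatment in the
    window [t, t + delta) months after launch.

    The stock decays exponentially with the given half-life, so the window
    fraction is ``2**(-t/lambda) - 2**(-(t+delta)/lambda)``.  Windows over a
    partition of [0, T) telescope to ``1 - 2**(-T/lambda)``.
    """
    if delta_months <= 0:
        raise ValueError("delta_months must be > 0")
    if half_life_lambda <= 0:
        raise ValueError("half_life_lambda must be > 0")
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    out = np.exp(-t * LN2 / half_life_lambda) - np.exp(
        -(t + delta_months) * LN2 / half_life_lambda
    )
    return out if out.ndim else float(out)


def half_life_from_first_year(first_year_fraction: float) -> float:
    """Half-life (months) such that ``first_year_fraction`` of the existing
    stock seeks treatment in the first 12 months: lambda = 12*ln2 / -ln(1-f).

    A fraction of 0.25 gives 28.91 months; 0.5 gives exactly 12.
    """
    if not (0.0 < first_year_fraction < 1.0):
        raise ValueError("first_year_fraction must lie in (0, 1)")
    return 12.0 * LN2 / (-math.log(1.0 - first_year_fraction))


def penetration(t_months, theta_max: float, t_max: float):
    """Ramp penetration rate: t*theta_max/t_max for t <= t_max, else theta_max."""
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    # clip the rising branch at the plateau so round-off at t == t_max can
    # never push the ramp above theta_max
    out = np.where(t <= t_max, np.minimum(t * theta_max / t_max, theta_max), theta_max)
    return out if out.ndim else float(out)


def draw_ramp_params(
    category: str,
    rng: np.random.Generator,
    dispersion: float = 0.10,
) -> RampParams:
    """Draw a ramp for a disease category.

    Draws are truncated-normal around the category means with standard
    deviation ``dispersion`` times the mean (moderate parameter uncertainty);
    theta_max is clipped to (0, 1] and t_max to positive values.
    ``dispersion=0`` returns the means exactly.
    """
    try:
        mu_theta, mu_t = RAMP_MEANS[category]
    except KeyError:
        raise ValueError(f"unknown category {category!r}; expected one of {sorted(RAMP_MEANS)}")
    if not (0.0 <= dispersion < 1.0):
        raise ValueError("dispersion must lie in [0, 1)")
    if dispersion == 0.0:
        return RampParams(mu_theta, mu_t)
    theta = float(rng.normal(mu_theta, dispersion * mu_theta))
    t_max = float(rng.normal(mu_t, dispersion * mu_t))
    theta = min(max(theta, 1e-12), 1.0)
    t_max = max(t_max, 1e-9)
    return RampParams(theta, t_max)


def patients_treated(
    month_t: float,
    new_patients_rate: float,
    existing_stock0: float,
    ramp: RampParams,
    uptake: UptakeParams,
    eligible_fraction: float = 1.0,
) -> float:
    """Patients treated in month ``month_t`` after approval.

    ``new_patients_rate`` is the monthly inflow of newly diagnosed patients;
    ``existing_stock0`` is the pre-approval stock.  Both streams pass through
    the penetration ramp and the eligibility fraction; the existing stream is
    additionally weighted by the one-month depletion window fraction.
    """
    if new_patients_rate < 0 or existing_stock0 < 0:
        raise ValueError("patient inputs must be >= 0")
    if not (0.0 < eligible_fraction <= 1.0):
        raise ValueError("eligible_fraction must lie in (0, 1]")
    rho = penetration(month_t, ramp.theta_max, ramp.t_max)
    frac = existing_fraction(month_t, 1.0, uptake.half_life_lambda)
    return rho * eligible_fraction * (new_patients_rate + frac * existing_stock0)
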