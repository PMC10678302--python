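"""Approval simulation: correlated program successes, trial-duration
imputation, and regulatory timing.

A disease obtains an approved therapy if at least one of its development
programs succeeds.  Program successes are correlated Bernoulli variables
generated through a Gaussian copula with a single exchangeable pairwise
correlation (default 0.9), reflecting shared platform risk across gene
therapy programs; the copula preserves each program's marginal
phase-3-to-approval probability of success (PoS), tabulated by therapeutic
area.

Approval timing: the sponsor files a biologics license application (BLA)
only after the disease's last trial has ended; BLA preparation and FDA
review each add a symmetric triangular lag on [0, 365] days with mode
182.5.  Trials missing end dates get them imputed from a gamma distribution
fitted by maximum likelihood to the complete trials' durations.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._dates import add_days, month_index
from .registry import Registry

__all__ = [
    "DEFAULT_POS_TABLE",
    "PRIOR_APPROVAL_DATE",
    "STALE_TRIAL_CUTOFF",
    "TimingModel",
    "ApprovalOutcome",
    "fit_duration_gamma",
    "impute_end_dates",
    "simulate_successes",
    "disease_approval",
]

#: Phase-3-to-approval probability of success by therapeutic area, from
#: path-by-path estimates over >55k drug development programs (2000–2020).
DEFAULT_POS_TABLE: dict[str, float] = {
    "Autoimmune/Inflammation": 0.485,
    "Cardiovascular": 0.501,
    "CNS": 0.370,
    "Metabolic/Endocrinology": 0.457,
    "Oncology": 0.285,
    "Ophthalmology": 0.459,
}

#: Diseases with an already-marketed therapy are treated as approved on this date.
PRIOR_APPROVAL_DATE = _dt.date(2020, 12, 31)

#: A disease whose last trial ended before this date with no launch observed
#: is treated as failed.
STALE_TRIAL_CUTOFF = _dt.date(2017, 1, 1)


@dataclass(frozen=True)
class TimingModel:
    """Regulatory lags and the trial-duration distribution.

    Both lags are triangular on [0, 365] days with mode (= median, by
    symmetry) 182.5; ``gamma_shape``/``gamma_scale`` parameterise imputed
    trial durations in days.  ``lag_scale_*`` multiply the lag draws and
    exist for sensitivity analysis.
    """

    tri_min: float = 0.0
    tri_mode: float = 182.5
    tri_max: float = 365.0
    gamma_shape: float | None = None
    gamma_scale: float | None = None
    lag_scale_bla: float = 1.0
    lag_scale_review: float = 1.0

    def draw_bla_prep(self, rng: np.random.Generator) -> float:
        return self.lag_scale_bla * float(
            rng.triangular(self.tri_min, self.tri_mode, self.tri_max)
        )

    def draw_fda_review(self, rng: np.random.Generator) -> float:
        return self.lag_scale_review * float(
            rng.triangular(self.tri_min, self.tri_mode, self.tri_max)
        )

    def with_gamma(self, shape: float, scale: float) -> "TimingModel":
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma parameters must be positive")
        return dataclasses.replace(self, gamma_shape=shape, gamma_scale=scale)


@dataclass(frozen=True)
class ApprovalOutcome:
    disease_id: str
    approved: bool
    approval_month: int | None = None  # month index, 0 = January 2020


def fit_duration_gamma(trials) -> tuple[float, float]:
    """Maximum-likelihood gamma fit (shape, scale) to trial durations in days.

    Only trials with both dates contribute.  Requires at least two complete
    trials and nondegenerate (non-identical) durations.
    """
    durations = np.array(
        [
            (t.end_date - t.start_date).days
            for t in trials
            if t.end_date is not None
        ],
        dtype=float,
    )
    durations = durations[durations > 0]
    if durations.size < 2:
        raise ValueError("need at least 2 complete trials with positive duration to fit")
    if np.ptp(durations) == 0:
        raise ValueError(
            "degenerate durations (all equal): gamma MLE diverges (shape -> inf)"
        )
    shape, _loc, scale = stats.gamma.fit(durations, floc=0)
    return float(shape), float(scale)


def impute_end_dates(
    registry: Registry, gamma: tuple[float, float], rng: np.random.Generator
) -> Registry:
    """Fill missing trial end dates with start + gamma-distributed duration."""
    shape, scale = gamma
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma parameters must be positive")
    out = registry.copy()
    for t in out.trials:
        if t.end_date is None:
            t.end_date = add_days(t.start_date, float(rng.gamma(shape, scale)))
    return out


def simulate_successes(
    programs,
    pos_table: dict[str, float] | None = None,
    correlation: float = 0.9,
    rng: np.random.Generator | None = None,
    pos_scale: float = 1.0,
) -> dict[str, bool]:
    """Draw correlated success flags, one per development program.

    ``programs`` is an iterable of (program_id, therapeutic_area) pairs or a
    DataFrame with those columns.  Latent standard normals share a single
    pairwise correlation rho (exchangeable one-factor structure:
    ``sqrt(rho)*Z + sqrt(1-rho)*eps_i``); program i succeeds iff its latent
    value falls below ``Phi^{-1}(PoS_i)``, so marginals equal the PoS table
    for every rho.  ``pos_scale`` multiplies the PoS values (clipped to 1)
    for sensitivity analysis.
    """
    if not (0.0 <= correlation <= 1.0):
        raise ValueError("correlation must lie in [0, 1]")
    pos_table = DEFAULT_POS_TABLE if pos_table is None else pos_table
    rng = np.random.default_rng() if rng is None else rng
    if hasattr(programs, "itertuples"):
        pairs = [(r.program_id, r.therapeutic_area) for r in programs.itertuples(index=False)]
    else:
        pairs = list(programs)
    m = len(pairs)
    pos = np.array([min(pos_table[area] * pos_scale, 1.0) for _, area in pairs])
    if np.any(pos < 0) or np.any(pos > 1):
        raise ValueError("PoS values must lie in [0, 1]")
    z = rng.standard_normal()
    eps = rng.standard_normal(m)
    latent = np.sqrt(correlation) * z + np.sqrt(1.0 - correlation) * eps
    flags = latent < stats.norm.ppf(pos)
    return {pid: bool(f) for (pid, _), f in zip(pairs, flags)}


def disease_approval(
    registry: Registry,
    success_flags: dict[str, bool],
    timing: TimingModel,
    rng: np.random.Generator,
    as_of: _dt.date = STALE_TRIAL_CUTOFF,
) -> dict[str, ApprovalOutcome]:
    """Resolve per-disease approval status and month.

    Rules, in order: a prior-approval disease is approved on the fixed
    prior-approval date; a disease whose last trial ended before ``as_of``
    (and has no prior approval) has failed; otherwise the disease is
    approved iff any of its programs succeeded, at the last trial end plus
    BLA-preparation and FDA-review lags.  Approval months earlier than the
    simulation start are floored at month 0.  All trials must carry end
    dates (impute first).
    """
    outcomes: dict[str, ApprovalOutcome] = {}
    for d in registry.diseases:
        trials = registry.trials_for(d.disease_id)
        if any(t.end_date is None for t in trials):
            raise ValueError(f"{d.disease_id}: missing end dates; run impute_end_dates first")
        if d.prior_approval:
            outcomes[d.disease_id] = ApprovalOutcome(
                d.disease_id, True, month_index(PRIOR_APPROVAL_DATE)
            )
            continue
        last_end = max(t.end_date for t in trials)
        if last_end < as_of:
            outcomes[d.disease_id] = ApprovalOutcome(d.disease_id, False)
            continue
        programs = {t.program_id for t in trials}
        # lags are drawn unconditionally so the rng stream stays aligned
        # across perturbed reruns sharing a seed (variance reduction)
        lag = timing.draw_bla_prep(rng) + timing.draw_fda_review(rng)
        if any(success_flags.get(p, False) for p in programs):
            month = max(0, month_index(add_days(last_end, lag)))
            outcomes[d.disease_id] = ApprovalOutcome(d.disease_id, True, month)
        else:
            outcomes[d.disease_id] = ApprovalOutcome(d.disease_id, False)
    return outcomes
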