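# Methods

## Scope and intent

`gtbudget` simulates the fiscal impact of a fixed snapshot of late-stage
gene-therapy development programs on U.S. health-care spending over a
15-year horizon (January 2020 – December 2034, month index 0 = January
2020). The unit of success/failure is the development program (one
sponsor, one therapeutic, one disease); the unit of spending is the
disease-month. The model deliberately excludes market competition between
therapies for one disease, patient-type heterogeneity, fast-tracking of
phase-1/2 programs, and any cost offsets from displaced standard of care.

## Approval model

Program success is Bernoulli with a phase-3-to-approval probability
(PoS₃ₐ) by therapeutic area:

| area | PoS₃ₐ |
|---|---|
| Autoimmune/Inflammation | 0.485 |
| Cardiovascular | 0.501 |
| CNS | 0.370 |
| Metabolic/Endocrinology | 0.457 |
| Oncology | 0.285 |
| Ophthalmology | 0.459 |

Dependence across programs is induced by a Gaussian copula with a single
exchangeable pairwise correlation ρ (default 0.9) implemented as a
one-factor latent structure `√ρ·Z + √(1−ρ)·εᵢ`; program *i* succeeds iff
its latent value falls below Φ⁻¹(PoSᵢ), so marginal success
probabilities are preserved for every ρ. Two open design points were
resolved as follows: the copula family is Gaussian (swappable; only weak
evidence constrains the choice), and the correlation is global across all
programs rather than within-disease only, which is the structure the
correlation sweep varies. Positive dependence lowers P(at least one
success per disease), so expected approvals and spending are
nonincreasing in ρ — a property the tests verify empirically.

Timing: a biologics license application is filed only after the
disease's last trial ends; BLA preparation and FDA review each add an
independent symmetric triangular lag on [0, 365] days with mode 182.5
(making the median 182.5 days as intended). Trials missing end dates get
`start + Gamma(shape, scale)` durations, with the gamma fitted by maximum
likelihood (location fixed at 0) to the registry's complete trials; the
fit refuses degenerate all-equal durations, where the MLE diverges.
Special rules: diseases with an already-marketed therapy are approved on
2020-12-31 (month 11); diseases whose last trial ended before 2017-01-01
(configurable) with no launch are failed. Computed approval dates that
precede January 2020 — possible for trials ending 2017–2019 with short
lags — are floored at month 0, since the reporting horizon starts there.

## Patients

Incidence *i* (persons/year) and prevalence *j* (persons) are linked at
demographic steady state by `j = k·i/(1−p)`, where *p* is the fraction
alive *k* years after diagnosis; whichever of the two a registry record
lacks is recovered from the other. Nested disease pairs (a parent and a
sub-indication) are de-overlapped once by subtracting child counts from
the parent; the adjustment is flagged on the registry so re-application
is a no-op.

After approval, monthly treated patients are

```
Patients_t = ρ(t, Θmax, Tmax) · e · [ i/12 + E(t, 1, λ) · j ]
```

with eligibility fraction *e* (default 1), a ramp ρ rising linearly to
Θmax at Tmax months, and the window depletion fraction
`E(t, δ, λ) = 2^(−t/λ) − 2^(−(t+δ)/λ)` applied to the pre-approval
stock. λ = 28.91 months is pinned by assuming 25% of the stock seeks
treatment in the first year (`λ = 12·ln2 / −ln 0.75`). The depletion
term is a closed-form function of time since approval (memoryless), not
a mutable stock: patients who "seek" treatment in a low-ramp month and
are not treated are lost rather than requeued. Consequently cumulative
treated existing patients are bounded by `j·Θmax·e`, and discounted
spending is monotone in the first-year uptake fraction only up to a
saturation point near the 25% baseline — faster-than-baseline uptake
concentrates demand in early months where the ramp is still low and
changes spending little (slightly negatively), while slower uptake
defers large amounts of treatment past the horizon. The uptake sweep
tests assert exactly this asymmetric shape.

Ramp parameters by disease category (means; draws are normal with
standard deviation = 10% of the mean — the conventional reading of a
"variance set to 10% of the mean" specification — truncated to Θmax ∈
(0, 1] and Tmax > 0; dispersion 0 yields the means exactly):

| category | Θmax | Tmax |
|---|---|---|
| rare | 0.40 | 6 months |
| general/chronic | 0.01 | 60 months |
| cancer | 0.10 | 12 months |

The depletion formula is implemented with the exponents `−t·ln2/λ` and
`−(t+δ)·ln2/λ`; this is the only form consistent with the anchor
calibration (25% in year one, ~95% within 10.5 years) and with windows
telescoping to `1 − 2^(−T/λ)`.

## Prices, spending, payers

Launch price = (price per ΔQALY) × ΔQALY. The rare-disease rate is the
through-origin least-squares slope `Σqᵢcᵢ/Σqᵢ²` over launched-therapy
calibration points (default: onasemnogene abeparvovec, 20.56 QALYs at
$2.1M; voretigene neparvovec, 4.63 QALYs at $0.425M per eye), giving
$101,641 on the rounded inputs and matching the published $101,663
within 0.1%. Fit diagnostics are reported both as totals (sum of squared
errors, sum of absolute percentage errors — the variant that reproduces
the published 2.18×10⁹ and 11.2% figures) and as means. The
other-disease rate $40,797/QALY is a fixed default: the CAR-T ΔQALY
inputs behind it are not public, so it is not re-derived. Cancers and
general diseases share the other-disease rate. Per-eye pricing is folded
into the "patient unit": the engine prices one unit per treated patient
and leaves units-per-patient as a registry-level choice (default 1).
Per-disease ΔQALY is a registry input; the synthetic generator draws
category-typical values (rare ~ U(5, 25); cancer/general ~ U(0.5, 5)).

Monthly spending is patients × price; QALYs are booked fully in the
treatment month (no amortization schedule is modelled). Spending is
split by each disease's minor/adult/elderly mix and decomposed into
payers on spending (not patient counts): Medicare = all elderly
spending, Medicaid = 2/5 of minor + 1/7 of adult spending, private = the
remainder. Discounting is monthly at an annual rate (default 3%/yr, the
standard health-economics base case; the rate is configuration, and
nominal series are always reported alongside).

## Monte Carlo and reproducibility

Each iteration draws its own imputation, copula, lag and ramp values
from a substream `SeedSequence(seed, spawn_key=(i,))`, so results are
independent of batching and bitwise reproducible. Reductions are the
elementwise mean and pointwise 5th/95th percentiles per calendar month.
Lag and ramp draws are consumed unconditionally (even for failed
diseases), keeping streams aligned across perturbed reruns that share a
seed; tornado deltas are therefore common-random-number differences, and
the two exactly-linear variables (price per ΔQALY, ΔQALY) reproduce the
±20% perturbation to machine precision with an unchanged peak month
(ties in the peak break toward the earlier month). Default iteration
counts are desk-scale: 10⁴ in the config default, 10²–4×10³ in tests and
examples, chosen so the full suite runs in about a minute; production
bands warrant 10⁵–10⁶.

## Synthetic registries

No public machine-readable pipeline snapshot exists, so
`generate_registry` builds registries with the documented structure:
category weights default to cancer 0.50 / rare 0.30 / general 0.20
(oncology-dominated, as in the late-2019 pipeline); 1–4 programs per
disease; ~20% of trials missing end dates (the true missingness rate is
unreported; configurable); at least one prior-approval disease and one
nested parent/child pair; trial starts 2015–2019 with 1–5-year
durations; prevalence log-uniform per category (rare 10²–10⁴, cancer
10³–10⁶, general 10⁵–10⁷ persons); a third of records carry only one of
incidence/prevalence to exercise the steady-state conversion. What the
generator does **not** emulate: real diseases' heavy-tailed epidemiology,
correlations between prevalence and ΔQALY, sponsor portfolios spanning
diseases, and registration lag. Passing tests therefore validate the
simulation machinery and its invariants on structurally realistic
inputs, not any specific published aggregate — headline dollar figures
depend on the actual (non-deposited) registry and are out of scope as
numeric targets.

## Numerical choices and edge cases

- The ramp's rising branch is clipped at Θmax so round-off at `t = Tmax`
  can never overshoot the plateau (keeps ρ exactly nondecreasing).
- Registry CSVs are parsed with round-trip float precision so
  write→read→write is byte-identical.
- An immortal cohort (p = 1) has no steady state and is rejected;
  PoS = 0 and PoS = 1 are allowed (never/always succeed).
- Age mixes must sum to 1 within 1e-9; payer shares given as rounded
  percentages are accepted within 1% and renormalised.
- `fit_sse`/`fit_sum_ape` are totals by default (with `fit_mse`/`fit_mape`
  mean variants) for consistency with the published diagnostics.

## Known limitations

- The memoryless depletion form (no requeueing) makes uptake-speed
  effects asymmetric, as described above; a stock-tracking variant would
  change the high-uptake tail.
- The exchangeable one-factor copula cannot express richer dependence
  (e.g. stronger within-platform correlation).
- Payer mapping is a static age-share approximation; eligibility,
  coverage restrictions and price negotiation are not modelled.
- Pipeline-extension arrivals inherit whole disease profiles from the
  baseline registry's empirical distribution, understating novelty in
  future indications.
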