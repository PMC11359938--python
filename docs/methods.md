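# Methods

## 1. Decision problem

A closed cohort of Chinese adults enters the model at age 50, 60, 70 or 80
under one of three strategies — no vaccination, one dose of live attenuated
zoster vaccine (ZVL), or two doses of recombinant subunit zoster vaccine
(RZV) — and is followed for 40 annual cycles. Outcomes are lifetime herpes
zoster (HZ) and postherpetic neuralgia (PHN) cases, discounted costs (USD)
and discounted quality-adjusted life years (QALYs), each reported per 1,000
cohort members. Strategies are compared by incremental cost-effectiveness
ratio (ICER) and net monetary benefit (NMB) at a willingness-to-pay (WTP)
threshold of one GDP per capita (12,681 USD per QALY).

## 2. Model structure

### 2.1 States and transitions

Six mutually exclusive states: `Healthy`, `AcuteHZ`, `PHN`,
`OtherComplication`, `HZResolved`, `Dead`. Each annual cycle:

1. **Mortality first.** Age-specific all-cause mortality `q(a)` applies to
   every living state (competing-risk, multiplicative ordering). `AcuteHZ`
   additionally carries an age-band case fatality applied to survivors of
   background mortality.
2. **Disease transitions among survivors.** From `Healthy` (and, scaled by a
   breakthrough multiplier, from `HZResolved` via recurrence), the HZ hazard
   is the age-band incidence multiplied by `(1 − VE(t))` where `VE(t)` is the
   strategy's waning efficacy at `t` years since vaccination. `AcuteHZ`
   occupies exactly one cycle and resolves to `PHN` (probability
   `p_phn_given_hz`), `OtherComplication` (`p_comp_given_hz`), or
   `HZResolved`. `PHN` and `OtherComplication` exit to `HZResolved` with
   configurable annual exit probabilities (default 1.0, i.e. one-year
   sequela duration).

Rows of the transition matrix are validated to be probability distributions;
`p_phn + p_comp > 1` raises an error rather than being renormalized silently.

### 2.2 Vaccine efficacy

Published trial efficacy anchors `(years since vaccination, VE)` per vaccine
and vaccination-age band are fit with ordinary least squares to a line
(exact closed form for two anchors). `VE(t)` is the fitted line clamped to
[0, 1]; it is extrapolated beyond follow-up and truncates at zero. The curve
band is the band at vaccination age and `t` is the cycle index, so protection
follows the vaccinated individual rather than the attained-age band.

RZV under two-dose compliance `c` uses the convex blend
`VE(t) = c·VE₂(t) + (1 − c)·VE₁(t)`, where the one-dose curve is the
two-dose curve scaled by `model.rzv_one_dose_factor` (default 0.9, an
assumption in the absence of one-dose waning data).

### 2.3 Costs and utilities

All vaccine acquisition and administration costs accrue at cycle 0:
ZVL pays `price + admin` once; RZV pays `(2c + (1 − c)) · (price + admin)`.
Disease costs (direct medical, non-medical, indirect categories) attach to
state occupancy: because `AcuteHZ` lasts one cycle, acute costs equal
episodes × unit cost; PHN and complication costs accrue per occupied year.
QALYs are occupancy-weighted `min(state utility, u_healthy(attained age))`,
so a sick state can never score above the age-matched background utility.

### 2.4 Discounting

Costs and QALYs discount at rate `r` (default 5%/year) with weights
`1/(1+r)^t`, `t` the cycle index (cycle 0 undiscounted). Case counts are
never discounted. An optional half-cycle correction (trapezoid weighting of
occupancy) is off by default to match the standard annual-cycle convention.

## 3. Base-case parameters

Published values (packaged in `data/basecase.yaml`):

| Parameter | Default | Units | Note |
|---|---|---|---|
| RZV price per dose | 453.55 | USD | |
| ZVL price per dose | 194.28 | USD | |
| Administration fee per dose | 4.24 | USD | |
| Exchange rate | 7.0467 | CNY/USD | used when a config is given in CNY |
| Acute HZ utility `u_hz` | 0.85 | — | required, no default |
| PHN utility `u_phn` | 0.74 | — | required, no default |
| Discount rate | 0.05 | /year | |
| WTP | 12,681 | USD/QALY | one GDP per capita |
| Two-dose compliance | 1.0 | — | scenario analysis varies 0.2–1.0 |
| ZVL efficacy anchors | 62.7 / 64.4 / 18.6 / 18.6 % at t=0 | — | by band, waning to 0 at 11 y |
| Horizon | 40 | years | lifetime for a cohort entering at ≥50 |

Values not printed in the source study's main text (age-band incidence, PHN
and complication risks, case fatality, recurrence, disease costs, background
utilities, the life table, and RZV anchor levels) are **plausible stand-ins**
labelled as such in `basecase.yaml`: incidence 0.0058–0.0120/year rising with
age, PHN risk 0.13–0.33, complication risk 0.08–0.14, case fatality
2×10⁻⁴–4×10⁻³, recurrence 0.005/year, a Gompertz life table (q₅₀ = 0.00295 to
q₁₀₀ = 0.436), acute/PHN/complication costs 385 / 1,650 / 820 USD plus
non-medical and indirect components, background utilities 0.91–0.78 falling
with age, and RZV anchors ≈ 0.97 at t=0 waning to ≈ 0.75 at 10 years. Any of
these can be replaced via a user config file or `--override`.

## 4. Sensitivity analyses

- **Tornado (one-way).** Each parameter in `owsa_spec` is set to its low and
  high bound; the bar is the ICER range against no vaccination. Bars sort by
  width; dominance outcomes map to NaN and are treated as zero-width.
- **PSA.** Each parameter in `psa_spec` draws from beta (probabilities,
  utilities, efficacy intercepts), gamma (costs), lognormal, uniform or point
  families; hyperparameters come either explicitly or by method of moments
  from `(base, low, high)` with `se = (high − low)/3.92`. Draws resample
  wholesale (up to 1,000 attempts) until the parameter set passes validation,
  preserving joint invariants. Draw order is fixed (sorted target paths) so a
  seed is bit-reproducible. The CEAC reports, on a WTP grid of 101 points
  from 0 to 3×WTP, the share of draws in which each strategy has the highest
  NMB (ties to the first of none/ZVL/RZV).
- **Compliance scenarios.** RZV ICER vs no vaccination for two-dose
  completion 20–100%, blending efficacy and dose cost as in §2.2–2.3.
- **ZVL price threshold.** NMB is affine in the ZVL dose price, so the price
  equalizing ZVL and RZV NMB has a closed form (verified against bisection in
  tests). If the crossing lies outside [0, base price] the result is flagged
  `not achievable by price alone` and the unconstrained crossing is reported.

## 5. Synthetic parameter generator

`make_synthetic_parameters(seed, difficulty)` produces fully valid parameter
sets for property-based testing: lognormal jitter (5% noise for `easy`, 20%
for `realistic`) around plausible bases, with monotonicity enforced
(incidence and PHN risk non-decreasing in age, background utility
non-increasing, `u_phn ≤ u_hz ≤ max u_healthy`), a jittered Gompertz life
table, efficacy anchors, and mirrored PSA/one-way specs. It emulates the
*shape* of a real evidence base — age gradients, orders of magnitude,
admissibility constraints — not any particular population; it does not model
parameter correlations or sampling uncertainty of real data sources.

## 6. Numerical choices

- Occupancy propagates by exact matrix-vector recursion in float64; row sums
  are defensively renormalized only against accumulated round-off, and tests
  check conservation to 1×10⁻¹⁰ and agreement with brute-force path
  enumeration to 1×10⁻¹² at short horizons.
- Two-anchor efficacy fits use the exact closed-form slope/intercept so that
  VE = 1 zeroes the hazard exactly; `np.polyfit` handles >2 anchors.
- Reported money values round half away from zero (so 114,980/25.24 prints
  as 4,556, not banker's 4,555); raw tables are also emitted unrounded.
- ICERs in dominance quadrants are returned as string markers
  (`comparator_dominant`, `comparator_dominated`, `undefined`) rather than
  signed ratios.

## 7. Open design decisions

- **Coverage interpretation.** The model evaluates a fully vaccinated cohort
  per strategy (the standard per-vaccinated-person CEA reading); the 30%
  population coverage figure is carried in the parameters but does not scale
  the per-1,000 results. Under this accounting, the full two-dose RZV outlay
  at printed prices (≈ 915,580 USD per 1,000) produces base-case ICERs far
  above one GDP per capita, and the packaged-base-case probabilistic analysis
  prefers no vaccination at that threshold. Published incremental costs of
  roughly 109,000–117,000 USD per 1,000 cannot be reconciled with those
  printed per-dose prices and near-complete case reduction under any
  coverage reading we found; the package keeps the internally consistent
  accounting rather than tuning inputs to reproduce the published totals.
- **Sequela duration.** PHN and other complications default to one-year
  duration (`phn_exit_prob = comp_exit_prob = 1.0`); chronic PHN can be
  modelled by lowering the exit probability.
- **One-dose RZV efficacy** is a scaled two-dose curve (factor 0.9) for lack
  of direct waning data.
- **Recurrence** uses a single age-independent annual probability with a
  breakthrough multiplier; VE applies to recurrent episodes as to first ones.

## 8. Limitations

- Stand-in values (§3) substitute for unpublished appendix inputs; absolute
  cost and QALY levels depend on them, though structural behaviour
  (dominance ordering, monotonicities, threshold logic) does not.
- Annual cycles cannot represent sub-annual acute-phase dynamics; acute HZ
  is a one-cycle state by construction.
- No herd immunity, no serious adverse events in the base case (hooks exist
  via `model.adverse_event_cost`/`_disutility`), and no revaccination.
- The societal perspective is limited to the cost categories configured;
  productivity effects beyond the indirect-cost inputs are not modelled.
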