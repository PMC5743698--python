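# Methods

## Model structure

A closed-cohort Markov state-transition model in weekly cycles. The five
reported health states are *no ulcer*, *ulcer*, *amputation*, *no ulcer
after amputation* and *ulcer after amputation*; the whole cohort starts in
*ulcer*. Mortality is excluded by design (the therapy is assumed to have
no influence on survival and background mortality is equal across arms),
so occupancy is conserved exactly; the engine enforces row sums of 1
within 1e−12 at every cycle and on every generated transition matrix.

Internally the state space is expanded:

- The acute post-amputation period is a **tunnel** of `t_tunnel = 4`
  weekly cycles (≈ 30 days; the nearest whole number of weekly cycles),
  during which the 0.500 utility multiplier applies. Tunnel occupancy
  advances deterministically and exits into the matching
  post-amputation no-ulcer state.
- Amputations are split into **small vs leg** at `leg_fraction = 0.1208`,
  the midpoint ratio of the annual national amputation counts
  (550 leg / (550 + 4,000 small) ≈ 12.09%). The split is carried through
  the tunnel and the two post-amputation branches so that utilities and
  costs can differ by amputation type; aggregation back to the five
  reported states is exact.

Transition routes: *ulcer* → heal or amputate (competing, remainder
stays); *no ulcer* → recurrence back to *ulcer*; post-amputation no-ulcer
→ post-amputation ulcer (same recurrence probability); post-amputation
ulcer → heal back, or **re-amputation** into a fresh tunnel with the same
leg/small split. Re-amputation is allowed by default because *ulcer after
amputation* is a live ulcer state and nothing in the model logic forbids
it; a deck flag (`structure.allow_reamputation`) closes the route. The
model does not allow amputation directly from a no-ulcer state.

Time is two-phase: arm-specific heal/amputation probabilities apply for
weeks 1–52 (the trial observation period); from week 53 both arms use the
comparator (GWC) probabilities, making the arms' transition matrices
bitwise identical after the phase boundary. The drug course length
(default 8 weeks) is a cost parameter only and is deliberately decoupled
from the 52-week efficacy phase; both are configurable. No half-cycle
correction is applied: state membership is valued at end of cycle. This
is a documented simplification — with weekly cycles the correction is
≤ 1/104 of a year of accumulation and identical in structure across arms,
so it largely cancels in the increments.

## Calibration

Cumulative 52-week proportions of first closure *c* and first amputation
*a* are converted to constant weekly cause-specific probabilities by
splitting the total weekly exit probability *s* = 1 − (1 − c − a)^(1/52)
proportionally: *p*_heal = *s·c/(c+a)*, *p*_amp = *s·a/(c+a)*. Because a
patient's exit cause is independent of the exit cycle under constant
probabilities, this closed form reproduces both cumulative incidences
exactly; `verify_calibration` confirms it by an independent 52-step
forward recursion with tolerance 1e−10, and *c + a ≥ 1* is rejected (a
certain exit has no constant-probability representation on a finite
horizon). Targets are interpreted as cumulative incidences of first
events, not week-52 point prevalences.

Recurrence reproduces the source rule verbatim: recurrent cases divided
by the pooled two-arm population (2/108), treated as a 52-week cumulative
proportion and converted the same way. This ignores person-time at risk
among the healed — a simplification inherited deliberately, and the main
reason the recurrence probability (≈ 3.59e−4/week) should be read as an
order of magnitude rather than an estimate.

## Valuation

Utilities are multiplicative on the 0.840/year reference value. Active
ulcer states are a within-state mixture of infected (10%) and
non-infected ulcers rather than separate Markov states. The non-infected
post-amputation ulcer multiplier is not part of the published set and is
composed multiplicatively (post-amputation no-ulcer multiplier × ulcer
multiplier), while the published infected post-amputation values (0.715
small, 0.620 leg) enter the mixture directly; multiplicative composition
is the table's evident convention and is flagged here as an assumption.
Every resulting per-cycle utility is bounded by the reference value.

Costs: weekly per-state payer costs (tunnel states share one entry per
amputation type); one-time amputation event costs charged — and
discounted — at tunnel entry (entrants are exactly the occupancy of the
first tunnel cycle); and the drug course, unit cost × units/week × course
weeks, charged undiscounted at model start to the treated arm only (the
course is ≤ 8 weeks, so within-course discounting is negligible). A deck
flag (`costs.prorate_drug_cost`) instead accrues the weekly drug spend
weighted by the fraction of the cohort still in the ulcer state,
discounted.

Discounting is per-cycle compound at 5%/year, factor (1.05)^(−(w−1)/52)
so that week 1 is undiscounted; an annual-step variant (constant factor
within each model year) is available behind `discount.annual_steps`
because the cycle-level convention is not dictated by an annual rate. The
per-cycle form is smooth and order-consistent with the annual rate; the
two differ by < 2.5% on any single cycle's factor.

ICER = ΔCost/ΔQALY when ΔQALY > 0; a negative ΔCost with positive ΔQALY
is reported as *dominant*, the reverse as *dominated*, and ΔQALY = 0
raises an explicit undefined-ICER signal rather than producing a number.
Verdicts against the statutory thresholds are boundary-inclusive:
ICER ≤ λ₁ reimbursable, λ₁ < ICER ≤ λ₂ conditionally reimbursable,
above λ₂ not cost-effective, with (λ₁, λ₂) = (24×, 35×) the average
monthly salary (deck default €858 → €20,592 / €30,030).

**Threshold price.** ΔCost is affine in the drug unit price, so the price
at which the ICER equals a threshold λ is
p\* = (λ·ΔQALY − ΔCost_nondrug)/slope. The pipeline measures intercept
and slope from two full runs (unit price 0 and 1), which keeps the
inversion exact under either drug-cost charging convention; the solution
is verified by re-running the pipeline at p\* (ICER = λ within 1e−6
relative). A non-positive p\* is reported as "no positive price achieves
the threshold".

## Sensitivity analysis

One-way deterministic: every scalar deck input — the five weekly
probabilities, leg fraction, all nine utility-table entries, all weekly
and event costs, the drug unit cost and the discount rate (27 parameters)
— is set to ×0.9 and ×1.1 of base, one at a time, with exactly two full
pipeline re-runs per parameter. Structural integers (horizons, tunnel
length, injections/week, course weeks) and the threshold salary are
excluded. Perturbed probabilities and multipliers are clamped to [0, 1];
a perturbed deck that still violates a cross-parameter constraint (e.g.
an infected-ulcer multiplier exceeding the non-infected one) is flagged
in the output table, never silently dropped. Entries are sorted by span
|ICER_high − ICER_low| descending, ties broken lexicographically; the
whole analysis is deterministic and repeated runs are byte-identical.
Probabilistic sensitivity analysis is out of scope.

## Synthetic data

The trial's patient-level data and the payer's per-state cost vectors are
not publicly available, so the generator produces stand-ins with the
structure the pipeline assumes; all generation is a pure function of an
integer seed, and the generator version and seed are embedded in outputs.

- **Trial cohorts**: per-patient weekly competing draws (heal vs amputate
  from ulcer as one categorical draw, avoiding within-week ordering
  artifacts; recurrence from healed; amputation absorbing at trial
  level), 54 patients/arm by default to mirror the 108-patient pooled
  population. Measured targets use the pooled recurrence rule.
- **Reference deck**: the published utility table, infected fraction
  0.10, leg fraction 0.1208, 5% discount and 5-/10-year horizons are
  fixed; 52-week targets are fixed at closure 0.70 / amputation 0.06
  (treated) vs 0.50 / 0.14 (comparator) — a plausible effect pattern in
  which treatment both closes more ulcers and prevents amputations;
  weekly costs are drawn once per seed from documented uniform ranges
  (e.g. ulcer care €150–250/week, acute tunnel €250–700/week, amputation
  events €2,500–4,500 small / €6,000–10,000 leg, drug €600–680 per
  injection at 3/week × 8 weeks ≈ €15k per course).

These choices make ten-year arm costs land in the tens-of-thousands-EUR
order of magnitude and the headline outputs reproduce the *qualitative*
published pattern — an ICER far above λ₂ that improves with horizon, the
post-small-amputation utility multiplier as the top sensitivity driver, a
threshold unit price in the low hundreds of euros. They are explicitly
not a reproduction of the original arm-level costs and QALYs, which
depended on unpublished trial proportions and payer data. What passing
tests show is that every pipeline stage is arithmetically correct and
internally consistent; they cannot show that the synthetic cost
magnitudes match Slovak payer reality.

## Numerical choices and problem sizes

Cohort fractions in double precision; conservation and row-stochasticity
tolerance 1e−12; calibration round trip 1e−10; threshold-price round trip
1e−6 relative; comparisons against published rounded table values 1e−3
relative. Horizons are 260 and 520 weekly cycles (5 and 10 years at 52
weeks/year). The parameter-recovery experiment simulates 1e5 patients per
arm and accepts estimates within three standard errors obtained by
propagating binomial target errors through the calibration map by central
differences. The test suite and the acceptance script each run in a few
seconds on one CPU.

## Known limitations

- No mortality, no half-cycle correction, constant (two-phase) hazards,
  and no memory beyond the acute tunnel.
- Re-amputation routes through a fresh tunnel whose leg/small split
  forgets the prior amputation type.
- The recurrence rule ignores time at risk (inherited deliberately).
- Synthetic cost magnitudes are realism aids, not payer data; absolute
  QALY/cost levels from the reference deck carry no external validity.
- Individual-level microsimulation, budget impact and probabilistic
  sensitivity analysis are non-goals.
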