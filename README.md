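# dfu-cea

A Markov cohort cost-utility model of an epidermal-growth-factor add-on
therapy (Heberprot-P) plus good wound care (GWC) versus GWC alone for
advanced (Wagner grade 3–4) diabetic foot ulcer, from a third-party
health-care payer's perspective. It is written for health economists and
HTA analysts who need a fully testable, scriptable version of this class
of model: transition-probability calibration from trial endpoints, a
weekly-cycle cohort engine, discounted QALY/cost accumulation, ICER and
reimbursement-threshold verdicts, threshold drug-price inversion, and a
one-way deterministic sensitivity analysis.

## The model

Five mutually exclusive health states — *no ulcer*, *ulcer* (the start
state for the whole cohort), *amputation*, *no ulcer after amputation*,
*ulcer after amputation* — simulated in weekly cycles without mortality,
so cohort occupancy is conserved exactly. Internally the amputation state
is a 4-week acute tunnel split into small vs leg amputations (12.08% leg),
and the after-amputation states carry the same split.

**Calibration.** The trial reports cumulative 52-week proportions of first
ulcer closure *c* and first amputation *a*. With total exit *E = c + a*,
the constant weekly exit probability is *s* = 1 − (1 − *E*)^(1/52), split
cause-specifically: *p*\_heal = *s·c/E*, *p*\_amp = *s·a/E*. This
reproduces both cumulative incidences exactly (verified by forward
simulation to 1e−10). Recurrence uses the pooled rule: 2 recurrent cases /
108 pooled patients as a 52-week cumulative proportion. Arm-specific
probabilities apply during the 52-week trial phase; afterwards both arms
take the comparator's probabilities.

**Valuation.** Utilities are multipliers on the 0.840/year reference value
of a diabetic patient with no ulcer (ulcer 0.890, infected ulcer 0.820
with a 10% infected mixture, post-small-amputation 0.830,
post-leg-amputation 0.730, acute post-amputation period 0.500). Costs are
weekly per-state payer costs plus one-time amputation event costs and the
drug course (unit cost × 3 injections/week × 8 weeks, treated arm only).
Both QALYs and costs are discounted at 5%/year, compounded per cycle.
ICER = ΔCost/ΔQALY is judged against the statutory thresholds
λ₁ = 24× and λ₂ = 35× the average monthly salary (€858 → €20,592 and
€30,030 per QALY).

The trial's patient-level data and the payer cost vectors are not public,
so a synthetic-data module generates a reference input deck (documented
cost ranges, arm targets with higher closure and lower amputation under
treatment) and simulated trial cohorts; the published utility table and
structural fractions are carried verbatim.

## Worked example

```sh
python analysis/01_simulate_trial.py --seed 1   # writes results/reference_deck.yaml
python analysis/02_calibrate.py
python analysis/03_run_model.py
python analysis/04_sensitivity.py
python analysis/05_threshold_price.py
```

On the seed-1 reference deck this prints (abridged):

```
gwc: p_heal=0.015200 p_amp=0.004256 p_rec=0.000359 roundtrip<1e-10: True

 horizon_years  delta_qaly   delta_cost  icer_eur_per_qaly            verdict
             5    0.080156 12493.489661      155864.103405 not_cost_effective
            10    0.135135 12061.120673       89252.534724 not_cost_effective

10y horizon: base ICER 89,253 EUR/QALY; top drivers:
  utilities.mult_post_small_no_ulcer: span 67,049 (low 66,918, high 133,966)

lambda2 (30,030 EUR/QALY): unit price 326.82 EUR (current 660.28); ICER at that price 30,030.0
```

Read: the treatment adds 0.135 QALYs per patient over ten years at an
incremental cost of ≈ €12,061, an ICER of ≈ €89,253/QALY — far above the
€30,030 upper threshold, so not cost-effective. The ICER *improves* with a
longer horizon because the incremental cost (dominated by the one-off drug
course) stays nearly constant while the utility gain from avoided
amputations keeps accruing. The most influential single input is the
utility multiplier for *no ulcer after small amputation*, and the drug
would need a unit price of ≈ €327 (down from €660) to meet the upper
threshold on this deck. All of these figures describe the synthetic
reference deck, not the original payer data.

The same stages are available as a CLI: `dfu-cea simulate | calibrate |
run | owsa | threshold-price | report`.

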