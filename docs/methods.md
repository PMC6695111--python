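# Methods

## Model structure

A four-state Markov state-transition model follows a cohort of children from
implantation at age 1 through age 84 in annual cycles.  The states are use
of the 1st/2nd/3rd internal cochlear-implant device and death; death is
absorbing and a maximum of two internal-device replacements is enforced
structurally (no failure or explantation transitions leave the third-device
state; wound revisions, which do not change state, may still occur there).

Within each cycle competing risks resolve mutually exclusively in a fixed
order: **death → major complication → internal failure**.  The order is a
modelling choice (the competing-risk tie-break is not identified by the
published description); because all event probabilities are small
(≤ 0.01/yr), reordering changes results only at the 4th decimal.  Both run
modes use exactly the same per-cycle distributions:

* **cohort mode** propagates occupancy expectations over the expanded state
  space (device index × years of use of the current device), which makes
  the time-dependent failure hazard exact rather than approximated by a
  mean device age;
* **microsimulation** samples individual trajectories with a seeded
  generator and reports Monte-Carlo standard errors.  A test requires the
  two modes to agree within 3 standard errors at n = 200,000.

## Transition probabilities

* **Mortality**: life-table q_x by single year of age.  The packaged table
  is synthetic — a Gompertz–Makeham law q_x = 1 − exp(−(A + B·c^age)) with
  A = 0.0002, c = 1.10, closed at age 100, and B calibrated by Brent root
  finding so that life expectancy at birth is 83.0 y (a high-longevity
  national population; computed as 0.5 + Σ l(a)).  Because mortality before
  age 55 is tiny under any such table, discounted results are insensitive
  to the exact table; users with a real `age,qx` table can supply it.
  No excess mortality is attached to deafness or surgery.
* **Major complications**: 0.01/yr in a device's first year, 0.001/yr
  thereafter, split half wound revision / half explantation with
  re-implantation.  The first-year rates re-apply in the first year after
  every (re)implantation — surgical risk is treated as per-procedure.  In
  the sequential arm no complications are attributed to the first implant:
  complication risk starts in the second implant's surgery year (age 3),
  which carries first-year rates.
* **Internal device failure**: annual hazard derived from cumulative device
  survival, q(t) = (S(t−1) − S(t))/S(t−1), with the clock t reset on
  replacement.  S is linear, S(t) = 0.998749 − 0.002911·t.  The printed
  form of this function ("0.002911 × Nth year + 0.998749") exceeds 1 if the
  slope is read as positive; the only reading consistent with survival data
  is a linear *decline* in cumulative survival, and that is what is
  implemented.  S is floored at 0.01 so hazards remain defined beyond year
  80.  The packaged 19-point "observed" curve lies exactly on this line
  (the raw manufacturer data are unavailable), so the OLS extrapolation fit
  recovers the coefficients to 6 decimals — by construction, which is what
  makes the fit operation exactly testable.

## Utilities

QALYs are accrued on the utility-*gain* scale (no-implantation baseline
normalised to 0): +0.232/yr for bimodal hearing and a further +0.03/yr for
bilateral implants, scaled by age band (28% at age 1, 91% at 2–3, 100% at
4–54, declining to 72% at 80–84).  The engine consumes the published
age-band cells verbatim; where a printed cell differs from scaling × base
by rounding (e.g. 0.066 vs 0.28 × 0.232 = 0.06496, or 0.027 vs 0.91 × 0.03
= 0.0273), the printed cell wins.  Validation checks printed-vs-derived
consistency to ±0.002 — the loosest printed-rounding discrepancy — rather
than an exact rounding rule, because the source's rounding convention is
not consistent across bands.  When a sensitivity analysis overrides a base
increment, the affected row switches to scaling × base so the override
propagates exactly; this makes the incremental QALY stream exactly
proportional to the bilateral base increment, which is why halving
0.03 → 0.015 doubles the ICER to numerical precision.

The bilateral addend applies only from the second implant's implantation
age (1 or 3).  Horizon ends with the last utility band at age 84; nothing
accrues beyond.  QALYs are discounted at mid-cycle (half-cycle correction
applied to QALYs only); costs at cycle start.  The annual discount rate is
3% for both.

## Costs

All computation is in 2017 USD (1 USD = 1.317 SGD retained for reporting
only; no inflation indexing).  The published resource schedule is
incremental (second implant vs bimodal).  Arm-level totals additionally
carry a reconstructed first-implant "backbone" — the same pathway mirrored
at years 1–3 — which is identical across arms and cancels exactly from
every pairwise increment (a test perturbs it and re-diffs).  Bimodal
hearing additionally replaces its acoustic hearing aid every 5 years;
bilateral arms replace one extra external processor every 7 years per
implant.  Periodic replacements fire strictly *after* their anchor year
(implantation year for processors, model start for the hearing aid): the
initial device of each kind is part of the acquisition, not a replacement,
and the sequential arm's contralateral aid in years 1–2 never reaches a
5-year replacement.

Event costs: wound revision = surgery + 1 ward day; explantation/failure
replacement = surgery + 1 ward day + a replacement device *only after the
10-year warranty* of the failed device.  Replacement-related costs are
doubled in bilateral arms (two independent ears with identical risks,
modelled as one device chain with a cost multiplier of 2, not as two
simulated ears).

Two costing parameters deserve flags:

* **External processor price** — absent from the published cost table.  It
  is reconstructed by calibrating the cohort-mode simultaneous-vs-bimodal
  incremental cost to its published value (USD 53,451), yielding
  USD 5,895.74, then held fixed everywhere.  The sequential incremental
  cost is then an out-of-sample check (computed: 62,403 vs published
  67,533, −7.6%).  The manifest marks the price as reconstructed.
* **Bilateral acquisition cost (DSA lever)** — the published one-way
  analysis varies "the cost of the initial bilateral cochlear
  implantation".  This is implemented as a multiplier on the device +
  implantation-surgery units of the bilateral arm's two initial
  acquisitions (≈ USD 66,300 at base), leaving the comparator and all
  replacement events untouched; ±10% then moves the simultaneous ICER by
  about ±12%, matching the published swing, which identifies the varied
  quantity as the full bilateral acquisition rather than the second device
  alone.

## Sensitivity analyses

**One-way DSA** re-runs cohort mode at each parameter's low/high, all else
at base, and sorts entries by ICER range.  The default plan varies the
bilateral utility increment over its literature range (0.015–0.06) and the
named cost drivers at ±10%; utility gain and acquisition cost dominate the
tornado, in that order.

**PSA** is second-order with 10,000 draws: every unit cost from a gamma and
both utility base increments from a beta, parameters by method of moments
with SD = CV × mean.  The default CV is 1.0, the literal reading of the
source's "standard deviation of each parameter was set to its mean"; it is
exposed as a parameter because that reading implies extreme dispersion
(a gamma with CV 1 is an exponential).  Infeasible beta moments are
truncated to 95% of the feasible bound with a warning.  Transition
probabilities are held fixed across draws.  Each draw is evaluated in
cohort mode; because the model is then *linear* in unit costs and utility
cells, a draw is computed exactly by reweighting one cohort run's loadings
(discounted expected units per cost item; discounted person-years per
utility band) — a test asserts draw-by-draw equality with the direct
override-and-rerun route.

**CEAC** optimality is net-monetary-benefit ranking (w × QALY − cost
strictly highest; ties split equally, so rows sum to 1).

A consequence worth stating plainly: with CV = 1 the cost-per-QALY
distribution is strongly right-skewed (the beta on the +0.03 increment has
median/mean ≈ 0.69), so the willingness-to-pay at which the bimodal and
simultaneous acceptability curves cross — essentially the *median* of that
distribution — sits 18–24% above the ratio-of-means base-case ICER
(≈ 72–76k vs 61.4k USD/QALY across seeds).  A PSA whose crossing coincides
with the base-case ICER requires materially smaller parameter dispersion
than the literal SD = mean reading.  The PSA *means* are unaffected and
track the deterministic base case within 0.3%.

## What the synthetic inputs do and do not show

The packaged life table emulates only the longevity of a high-income
national population (e0 = 83 y), not its age-specific shape at young ages;
the reliability fixture encodes the published extrapolation line, not real
manufacturer follow-up with its early-year curvature.  Tests passing on
these fixtures therefore demonstrate that the *model logic* reproduces the
published QALY results and sensitivity structure, not that the underlying
epidemiology or device reliability has been independently validated.
Arm-level cost totals depend on the reconstructed backbone and processor
price and are reported but not treated as reproductions.

## Numerical choices

* Root finding (life-table calibration, processor price) uses Brent's
  method; calibration tolerance 1e-12 on log10(B), 1e-6 USD on the price.
* Transition rows sum to 1 within 1e-12 (tested); occupancy stays a
  distribution each cycle within 1e-9.
* Reconstructing S from annual hazards reproduces the source curve within
  1e-9 at every observed year.
* Microsimulation draws three uniforms per individual per cycle in a fixed
  order (death, complication, failure) from one seeded generator, so
  results are bit-identical for identical (parameters, arm, n, seed).
* Degenerate inputs: q_x at the table's closing age is coerced to 1; ages
  beyond the table return q_x = 1; a survival of 0 yields a hazard of 1;
  zero-range DSA entries produce zero-width bars.

## Known limitations

* One device chain with doubled replacement costs, not two correlated ears.
* No voluntary non-use, no audiometric (dB) modelling, no education or
  productivity outcomes, no charge-vs-cost split, no inflation.
* External-device failures other than scheduled 7-year upgrades are not
  modelled.
* The first-year major-complication probability cell is unreadable in the
  source; 0.01/yr is inferred as the sum of its printed halves.
* Arm-level cost totals (e.g. the bimodal arm's lifetime cost) are not
  identifiable from the published text and should not be quoted as
  reproductions; only increments are anchored.
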