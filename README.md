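# cochlear-cea

Cost-effectiveness model of **bilateral cochlear implantation versus bimodal
hearing** (one cochlear implant plus a contralateral acoustic hearing aid) in
children with severe-to-profound sensorineural hearing loss in both ears,
from a healthcare-payer perspective.  The package is aimed at health
economists and HTA analysts who want a fully scripted, testable
re-implementation of this class of decision model: a four-state Markov
state-transition model with cohort-expectation and microsimulation engines,
one-way deterministic sensitivity analysis (tornado), second-order
probabilistic sensitivity analysis and cost-effectiveness acceptability
curves.

## The model

Three strategies are compared pairwise against bimodal hearing as the
comparator:

* **simultaneous** bilateral implantation — both implants at age 1;
* **sequential** bilateral implantation — first implant at age 1, second at
  age 3.

Each patient occupies one of four health states: *use of 1st internal
device*, *use of 2nd internal device*, *use of 3rd internal device*, *death*
(all-cause).  Annual cycles run from age 1 through age 84.  Within a cycle,
competing events resolve in a fixed order: death (life-table q<sub>x</sub>),
then a major surgical complication (half wound revision, which leaves the
state unchanged; half explantation with re-implantation, which advances the
device chain), then internal device failure, with the time-dependent hazard

&nbsp;&nbsp;&nbsp;&nbsp;q(t) = [S(t−1) − S(t)] / S(t−1),&nbsp;&nbsp;
S(t) = 0.998749 − 0.002911·t,

where t is years of use of the *current* device (the clock resets on every
replacement).  At most two internal replacements occur over a lifetime.
QALYs are accrued as age-banded utility *gains* over no implantation
(+0.232/yr bimodal; a further +0.03/yr for bilateral implants, scaled by age
band), discounted at 3%/yr with a half-cycle correction applied to QALYs
only; costs (2017 USD) are discounted from cycle start.  The headline
statistic is the incremental cost-effectiveness ratio
ICER = ΔC/ΔE (USD per QALY gained).

Two inputs of the original analysis are not published and are reconstructed
(and clearly flagged as such in the fixture manifest): the national life
table is replaced by a Gompertz–Makeham table calibrated to life expectancy
83 y, and the external sound-processor replacement price is calibrated so the
simultaneous-arm incremental cost matches its published value.

## Worked example

```python
from cochlear_cea import base_case, default_parameters, default_life_table

res = base_case(default_parameters(), default_life_table())
for arm, r in res["arms"].items():
    print(f"{arm.value:13s} cost={r.discounted_cost:10,.0f}  "
          f"QALY={r.discounted_qaly:.3f}")
ic = res["simultaneous_vs_bimodal"]
print(f"simultaneous vs bimodal: dC={ic.delta_cost:,.0f} "
      f"dQ={ic.delta_qaly:.3f} ICER={ic.icer:,.0f} USD/QALY")
```

prints

```
bimodal       cost=    76,914  QALY=6.733
simultaneous  cost=   130,365  QALY=7.604
sequential    cost=   139,317  QALY=7.569
simultaneous vs bimodal: dC=53,451 dQ=0.870 ICER=61,410 USD/QALY
```

i.e. either bilateral strategy yields more QALYs at a higher cost than
bimodal hearing; the sequential strategy accrues fewer QALYs (the second
implant arrives two years later) at a higher cost (extra surgery and three
years of habilitation) than the simultaneous strategy, so its ICER
(74,670 USD/QALY here) is always the worse of the two.

The numbered drivers under `analysis/` run the full study end to end and
write their tables under `results/`:

```bash
python analysis/01_build_inputs.py    # synthetic life table, reliability curve
python analysis/02_base_case.py       # arm totals + pairwise ICERs
python analysis/03_tornado.py         # one-way DSA tables
python analysis/04_psa_ceac.py        # 10,000-draw PSA + CEACs
python analysis/05_microsim_check.py  # microsimulation vs cohort expectation
```

The same pipeline is available from a shell via the `cochlear-cea` CLI
(`base-case`, `dsa`, `psa`, `ceac`, `make-fixtures`; see `--help`).

## Layout

* `src/cochlear_cea/` — the library: `parameters`, `life_table`,
  `device_reliability`, `markov_engine`, `costing`, `econ_analysis`,
  `synthetic_fixtures`, `cli`.
* `src/cochlear_cea/fixtures/` — packaged parameter file mirroring the
  published tables, synthetic life table, reliability curve, provenance
  manifest.
* `analysis/` — numbered narrative drivers.
* `docs/methods.md` — model assumptions, numerical choices, limitations.
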