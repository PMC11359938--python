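# zoster-cea

Cost-effectiveness analysis of herpes zoster (shingles) vaccination for
Chinese adults aged 50 and older, comparing three strategies:

1. **No vaccination**
2. **ZVL** — a single dose of live attenuated zoster vaccine
3. **RZV** — two doses of recombinant subunit zoster vaccine

The package implements a decision tree feeding an annual-cycle Markov cohort
model, computes incremental cost-effectiveness ratios (ICERs) and net monetary
benefit against a willingness-to-pay threshold of one GDP per capita
(12,681 USD), and ships four sensitivity analyses: one-way tornado,
probabilistic sensitivity analysis (PSA) with cost-effectiveness acceptability
curves, two-dose compliance scenarios, and a ZVL price-threshold analysis.

## The model in brief

A unit cohort starts Healthy at age 50, 60, 70 or 80 and is followed for
40 annual cycles through six states: Healthy, Acute herpes zoster (HZ),
Postherpetic neuralgia (PHN), Other complication, HZ resolved, and Dead.
Each cycle, age-specific all-cause mortality applies first; survivors then
move according to age-band incidence, PHN and complication risks, and an
acute-phase case fatality. Vaccine efficacy wanes linearly from published
trial anchors (fit per vaccine and vaccination-age band, clamped to [0, 1])
and multiplies the HZ hazard as `(1 − VE(t))`. RZV protection under partial
two-dose compliance `c` blends the two-dose and one-dose curves as
`c·VE₂(t) + (1 − c)·VE₁(t)`; dose acquisition and administration costs scale
accordingly at cycle 0. Costs attach to state occupancy; QALYs use
age-dependent background utility capped state utilities. Costs and QALYs are
discounted at 5% per year. Results are reported per 1,000 cohort members.

See [docs/methods.md](docs/methods.md) for assumptions, parameter tables,
and numerical details.

## Worked example

Command line (uses the packaged base-case parameters):

```bash
zoster-cea basecase --ages 50,60,70,80 --out results/
```

`results/basecase.csv` (costs in USD, rounded for reporting):

```text
 start_age       strategy  cases_per_1000  phn_per_1000  cost_per_1000  qalys_per_1000  incremental_cost  incremental_qalys     icer
        50 no_vaccination             233            48         117393        13791.85                                             
        50            zvl             213            46         298537        13793.39          181143.0               1.55 116986.0
        50            rzv              92            21         951335        13797.17          833942.0               5.33 156542.0
        60 no_vaccination             198            46         129202        11327.64                                             
        60            zvl             170            41         301394        11329.18          172193.0               1.54 111676.0
        60            rzv              60            15         946457        11331.99          817255.0               4.35 187798.0
        70 no_vaccination             145            38         121243         8362.84                                             
        70            zvl             136            36         309836         8363.14          188593.0               0.29 640645.0
        70            rzv              38            10         942787         8365.29          821544.0               2.45 335272.0
        80 no_vaccination              90            26          90626         5375.49                                             
        80            zvl              81            23         278766         5375.69          188140.0               0.21 909364.0
        80            rzv              17             5         930900         5376.91          840274.0               1.42 591004.0
```

The same analysis from Python:

```python
from zoster_cea import default_parameters, evaluate_all, Strategy
from zoster_cea.cea import compare

params = default_parameters()
res = evaluate_all(params, start_age=60)
cmp_ = compare(res[Strategy.NONE], res[Strategy.RZV], params.economics.wtp)
print(round(cmp_.icer))          # 187798 USD per QALY
print(res[Strategy.NONE].cases_per_1000)   # 197.66 lifetime HZ cases per 1000
print(res[Strategy.RZV].cases_per_1000)    # 59.60 — about 70% averted
```

Sensitivity analyses:

```bash
zoster-cea sens --mode tornado   --ages 60 --out results/tornado
zoster-cea sens --mode psa       --ages 60 --seed 42 --n-draws 10000 --out results/psa
zoster-cea sens --mode compliance --rates 0.2,0.4,0.6,0.8,1.0 --out results/compliance
zoster-cea sens --mode threshold --out results/threshold
```

With the packaged base-case prices, RZV lifetime cases averted range from 61%
(age 50) to 81% (age 80), but the full two-dose outlay (about 915,580 USD per
1,000 vaccinated) keeps both vaccination strategies above the one-GDP
willingness-to-pay threshold; the threshold analysis reports that no ZVL price
reduction alone makes ZVL the preferred strategy at base settings
(`not achievable by price alone`). Alternative price and coverage scenarios
can be explored with `--override`, e.g.
`--override costs.price_rzv_dose=50`.

## Repository layout

- `src/zoster_cea/` — parameters and validation (`params`), efficacy waning
  (`efficacy`), Markov engine (`cohort`), CEA metrics and frontier (`cea`),
  synthetic parameter generation and PSA draws (`synthetic`), sensitivity
  analyses (`sensitivity`), reporting (`report`), CLI (`cli`)
- `src/zoster_cea/data/basecase.yaml` — packaged base-case parameters
- `tests/` — unit, property-based and end-to-end acceptance tests
- `docs/methods.md` — model documentation
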