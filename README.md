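# gailsbsp

Gail-type 5-year absolute invasive breast-cancer risk models recalibrated
for South-East Asian (Singapore) populations — Chinese, Malay and Indian —
together with the calibration (expected/observed) and discrimination
(concordance) machinery used to validate such models, and a self-consistent
synthetic-cohort simulator.

The original Gail model projects a woman's absolute risk of invasive breast
cancer from a handful of questionnaire factors (age at menarche, age at
first live birth, affected first-degree relatives, benign biopsies) and
US Caucasian baseline rates. Applied unchanged to Singaporean women it
overestimates risk substantially, because both breast-cancer incidence and
competing mortality are much lower there. This package implements the
recalibrated family:

* **gail-sbsp** — original coefficients with Singapore race-specific
  incidence and competing-mortality rates;
* **s-gail-sbsp** — a simplified three-factor model (menarche age, age at
  first live birth, family history) with locally estimated coefficients;
* **e-gail-sbsp** — an extended model adding body-mass index (WHO Asian
  cuts) and parity, with locally estimated attributable risks;
* **bcddp** — the original US model, for comparison.

## The model

For a woman of age *a* with relative risk *r*ᵢ (the age stratum *i* splits
at 50 years), the probability of invasive breast cancer within *h* years
under the competing risk of death from other causes is

P(a, a+h) = Σⱼ [bⱼrᵢ / (bⱼrᵢ + cⱼ)] · S(sⱼ) · C(sⱼ) · (1 − e^{−δⱼ(bⱼrᵢ + cⱼ)})

summed over the 5-year age intervals *j* overlapping [a, a+h), where
*bⱼ* = *Bⱼ*(1 − AR(*i*))/10⁵ is the attributable-risk-deflated baseline
incidence, *cⱼ* the other-cause mortality hazard, *S* and *C* the
cancer-free and death-free survivals from *a*, and δⱼ the time spent in
interval *j*. The relative risk is *r*ᵢ = exp(β·x) over the coded factors,
with any interaction terms entering as products of codes. Both *r*ᵢ and
the attributable-risk fraction switch stratum if the projection crosses
age 50.

## Worked example

```python
from gailsbsp import (RawRecord, absolute_risk, builtin_coefficients,
                      builtin_rate_table, make_profile)

record = RawRecord(id="example", entry_age=50, ethnicity="sg-chinese",
                   age_menarche=13, age_first_live_birth=27,
                   n_first_degree_relatives=0)
profile = make_profile(record, model="s-gail-sbsp")
proj = absolute_risk(profile, builtin_coefficients("s-gail-sbsp"),
                     builtin_rate_table("sg-chinese"), h=5)
```

Running `python examples/01_project_individual_risk.py` prints:

```
relative risk (age <50 / >=50): 1.829 / 1.829
P(invasive breast cancer within 5y): 0.9240%
P(death from other causes first):    0.8183%
P(neither event):                    98.2577%
```

Menarche at 12–13 and a first birth at 25–29 multiply the referent hazard
by exp(0.238 + 2·0.183) ≈ 1.83; applied to the Chinese age-specific rates
this woman's 5-year absolute risk is about 0.92%, and the three
probabilities partition certainty. The other `examples/` scripts print the
relative-risk grids, an expected/observed calibration study with decile
table, and the size-weighted age-specific concordance on synthetic cohorts.

A thin command-line layer wraps the same functions:

```bash
gailsbsp rr-table --model s-gail-sbsp
gailsbsp simulate --n 30000 --seed 7 -o cohort.csv
gailsbsp predict --model gail-sbsp --rates sg-overall cohort.csv -o risks.csv
gailsbsp validate --model gail-sbsp --group-by age-band cohort.csv
gailsbsp params export --dest params/
```

## Scope

Coefficients and attributable risks are consumed as published; the package
does not refit them, and projections are limited to ages 20–90 (the
support of the rate tables). See `docs/methods.md` for the model details,
numerical choices and the simulator's fidelity limits.
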