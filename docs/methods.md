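# Methods

## Model structure

The package projects absolute invasive breast-cancer risk with the
classical two-component Gail construction:

1. **Relative risk.** Each woman's raw factors are coded into small
   integer categories (see *Coding*, below) and combined multiplicatively,
   r = exp(Σₖ βₖxₖ + Σ βₖₘxₖxₘ). Codes enter the linear predictor
   numerically (category 2 contributes 2β), as in the original model; the
   two interaction terms of the US model (biopsies × age category, first
   birth × family history) are products of codes. The age category
   (agecat, split at 50 years) indexes the relative-risk stratum: models
   that include agecat as a factor have genuinely different r below and
   above 50.

2. **Absolute risk under competing mortality.** Age-specific composite
   incidence B_j is deflated to a referent-profile baseline
   b_j = B_j(1 − AR)/10⁵ with the attributable-risk fraction AR of the
   relevant age stratum, then scaled by r. With other-cause mortality
   hazard c_j = C_j/10⁵, both hazards piecewise constant on the rate
   table's 5-year intervals, the probability that breast cancer occurs
   first within the horizon is the sum of per-interval terms
   (λ/(λ+μ))·S·(1−e^{−δ(λ+μ)}), with S the event-free survival accumulated
   from the start age. The symmetric term with μ/(λ+μ) gives the
   probability of dying of another cause first; the residual survival is
   the event-free probability. The three sum to one exactly (to double
   precision rounding), which the suite asserts at 1e-12.

The published evaluation assumes the start age lies on an interval
boundary and uses full 5-year exposures. The implementation generalises to
arbitrary start age and horizon by splitting [a, a+h) at every interval
boundary *and* at age 50 (so the relative-risk and AR strata can switch
mid-projection), and using the exact exposure δ per segment. On
boundary-aligned input this reduces to the published form; the
generalisation is validated against independent numerical quadrature of
the cause-specific density (agreement < 1e-8 on randomized parameter
draws) and against Monte-Carlo simulation (3 SE at n = 10⁶).

Survivals are accumulated from the start age (S(a) = C(a) = 1) rather
than from birth; this is algebraically identical to the published ratio
form S(τ)/S(a) but avoids multiplying fifteen intervals of survival.
Segments with zero total hazard contribute nothing and leave survival
unchanged (the 0/0 factor is taken as 0, consistent with the λ→0 limit).

## Parameters

* **Rate tables** (per 100,000 woman-years, stored exactly as published;
  the engine divides by 10⁵ at use): fifteen 5-year intervals with upper
  bounds 20, 25, …, 90 for US Caucasian 1983–87 and Singapore 2003–07
  (overall, Chinese, Malay, Indian). The open-ended ≥85 interval is given
  nominal width 5, so projections are refused beyond age 90.
* **Coefficient sets**: bcddp, gail-sbsp (US coefficients, Singapore
  rates; biopsy history collapsed to ever/never; atypical hyperplasia
  excluded as unobservable), s-gail-sbsp (three factors), e-gail-sbsp
  (adds BMI and parity). Attributable-risk pairs (under-50 / 50-plus):
  0.4771/0.4736 for the US-derived sets and 0.5356/0.5397 for the
  extended Singapore model. The published record does not state which
  pair the simplified model's projections used; it defaults to the US
  pair (consistent with its near-identical cohort-level expected count to
  gail-sbsp) and the pair is overridable via `CoefficientSet.with_ar`.
* The bcddp set ships the atypical-hyperplasia coefficient (0.57405);
  unknown status contributes zero to the linear predictor, matching the
  historical "code 99 = unknown" convention.

## Coding

Category cuts are closed on the printed lower edge: age 50 → upper age
stratum, BMI 23.0 → middle class, 27.5 → upper class (WHO Asian cuts).
Ages are whole years; no fractional-age interpolation. Unknown values map
to the referent code and never raise — the conventional behaviour of
Gail-style risk tools — except age-at-first-live-birth, whose referent
structure makes "25–29 or nulliparous" the conventional unknown bucket
(code 2, configurable via `unknown_ageflb_code`). Records are rejected as
contradictory when nulliparity coexists with positive parity, or a
recorded first-birth age with parity 0.

## Calibration and discrimination

* E = Σ predicted risks; the E/O interval is (E/O)·exp(±1.96·√(1/O)) with
  z fixed at 1.96 for bit-exact reproduction of the published intervals;
  rows with O = 0 have an undefined ratio/interval (printed as a dash in
  the source tables).
* Goodness of fit is Σ(O−E)²/E on **k** degrees of freedom (the number of
  categories, not k−1), and df = 1 for a single pooled row. This is a
  deliberate deviation from the usual Pearson convention: it is the
  published methodology and is the only choice that reproduces the
  published p-values (0.957, 0.959, 0.004 overall; 0.092 by age band).
* AUC is the rank-based concordance probability with midranks for ties.
  Because AUC is invariant under strictly monotone transforms, computing
  it on raw predicted risks is equivalent to the published procedure of
  first regressing case status on the risks — an equivalence the suite
  tests. The variance estimator is not stated in the source;
  Hanley–McNeil is the default, with DeLong available
  (`auc(..., variance="delong")`).
* The weighted concordance averages age-band AUCs with weights
  proportional to band size (renormalised over informative bands);
  variance = Σ w²·var; bands without both a case and a non-case are
  excluded. Deciles of predicted risk use stable ordering for ties and
  give the remainder rows to the lowest deciles.

## Synthetic cohorts

The simulator emulates the screening cohort the models were validated on:

* category prevalences from the published totals — menarche-age
  62.19/33.60/4.22%, the age-at-first-birth × family-history joint cells
  as printed (missing cells = 0), BMI 36.82/43.06/20.12% (normalised over
  the 1,635 women with known BMI), parity 65.0/23.7/11.3%, any-biopsy
  prevalence 1,707/28,883;
* entry ages proportional to the followed bands (109 / 13,911 / 14,642 /
  221 across 45–49/50–59/60–69/70–74), uniform whole years within a band;
* ethnicity proportional to the followed totals (24,339 Chinese, 1,619
  Malay, 1,422 Indian).

Factors are independent apart from the printed joint and one structural
coupling: nulliparity is only compatible with the "25–29 or nulliparous"
first-birth bucket, so parity 0 is drawn inside that bucket with
probability (185/1637)/(610/1637), preserving both published marginals
while keeping every record internally consistent. Raw values behind each
category (e.g. an actual menarche age for code 1) are drawn uniformly
from representative in-category ranges.

Outcomes are inverse-transform samples of piecewise-exponential cancer
and other-death times with exactly the hazards the engine assumes, so the
simulator is a Monte-Carlo oracle for the projection formula and a
self-consistent test bed for the calibration machinery. What passing the
self-consistency checks shows is that the engine, the simulator and the
validation statistics agree with each other and with the published
arithmetic — not that the models are well calibrated on real South-East
Asian women, which only independent cohort data can show. Known fidelity
gaps: no 3-year event-free selection (the source cohort started its clock
three years after a negative screen, so its women are lower-risk than an
unselected population), no calendar trends, no screening lead time, no
left truncation, and within-category homogeneity of risk.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state. The heavier checks in the
suite use n = 10⁶ Monte-Carlo draws per profile for engine agreement
(3 SE), 100 replicates of n = 30,000 for cohort-level E/O
self-consistency (≥95/100 intervals covering 1), and n = 30,000 cohorts
for concordance bracketing — sizes chosen to keep Monte-Carlo error well
below the tolerances being asserted while the full suite stays
conveniently fast.
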