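"""Absolute-risk projection engine.

Combines a coded :class:`~gailsbsp.coding.RiskProfile` with a coefficient
set and an age-specific rate table to project the probability of invasive
breast cancer over a horizon, under the competing risk of death from other
causes.

The hazard model is piecewise constant on the rate table's age intervals.
For a woman of current age ``a`` in relative-risk stratum ``i`` (the binary
current-age split at 50), the cancer hazard on interval ``j`` is
``b_j * r_ij`` with baseline ``b_j = B_j * (1 - AR_i) / 1e5``: the composite
incidence ``B_j`` deflated by the attributable-risk fraction so that it
applies to a referent-profile woman, scaled up by her relative risk
``r_ij = exp(beta . x)``.  The competing mortality hazard is
``c_j / 1e5``.  The probability of a breast-cancer diagnosis in
``[a, a + h)`` is then the sum over the intervals overlapping the horizon of

    (b_j r / (b_j r + c_j)) * S(s_j) * C(s_j) * (1 - exp(-d_j (b_j r + c_j)))

where ``s_j`` is where the horizon enters interval ``j``, ``d_j`` the time
spent in it, and ``S``/``C`` the cancer-free and other-death-free survivals
from ``a`` to ``s_j`` under the same hazards.  With ``a`` on an interval
boundary and ``h = 5`` this is the classical 5-year formula; the
per-interval exposures ``d_j`` generalise it to arbitrary ``a`` and ``h``.
Both the relative risk and the attributable-risk fraction switch stratum
when the projection crosses age 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import RiskProfile, code_cohort
from .params import CoefficientSet, RateTable, builtin_coefficients, builtin_rate_table

__all__ = [
    "EngineError",
    "RiskProjection",
    "linear_predictor",
    "relative_risk",
    "baseline_hazard",
    "absolute_risk",
    "rr_table",
    "predict_cohort",
]

AGE_SPLIT = 50.0  # agecat boundary: relative risk and AR switch stratum here


class EngineError(ValueError):
    """Invalid projection request (age outside table support, bad horizon...)."""


@dataclass(frozen=True)
class RiskProjection:
    """Decomposition of a woman's outcome probabilities over ``[a, a+h)``.

    ``trace`` records, per projection segment, the interval index, segment
    start age, exposure in years, and the cancer / other-death hazards
    (per year) applied on it.
    """

    p_breast_cancer: float
    p_other_death: float
    p_event_free: float
    start_age: float
    horizon: float
    r_under50: float
    r_50plus: float
    trace: tuple[tuple[int, float, float, float, float], ...]

    def __post_init__(self) -> None:
        total = self.p_breast_cancer + self.p_other_death + self.p_event_free
        if abs(total - 1.0) > 1e-12:
            raise EngineError(f"probabilities sum to {total}, not 1")


def linear_predictor(profile: RiskProfile, coeffs: CoefficientSet,
                     agecat: Optional[int] = None) -> float:
    """beta . x for a coded profile; unknown factors contribute 0."""
    lp = 0.0
    for factor, beta in coeffs.betas.items():
        x = profile.code(factor, agecat)
        if x is not None:
            lp += beta * x
    for (fa, fb), beta in coeffs.interactions:
        xa, xb = profile.code(fa, agecat), profile.code(fb, agecat)
        if xa is not None and xb is not None:
            lp += beta * xa * xb
    return lp


def relative_risk(profile: RiskProfile, coeffs: CoefficientSet,
                  agecat: Optional[int] = None) -> float:
    """Multiplicative relative risk exp(beta . x) for the given age stratum
    (defaults to the profile's own agecat)."""
    return float(np.exp(linear_predictor(profile, coeffs, agecat)))


def baseline_hazard(rates: RateTable, coeffs: CoefficientSet,
                    j: int, agecat: int) -> float:
    """Referent-profile cancer hazard b_j = B_j (1 - AR(agecat)) / 1e5,
    per woman-year, on interval ``j`` (1-based)."""
    if not (1 <= j <= len(rates.upper_bounds)):
        raise EngineError(f"interval index {j} outside 1..{len(rates.upper_bounds)}")
    return rates.breast_incidence[j - 1] * (1.0 - coeffs.attributable_risk(agecat)) / 1e5


def _segments(rates: RateTable, a: float, h: float):
    """Split [a, a+h) at interval boundaries and at the age-50 stratum
    switch; yield (j, start, delta, agecat)."""
    end = a + h
    cuts = {a, end}
    for tau in rates.upper_bounds:
        if a < tau < end:
            cuts.add(float(tau))
    if a < AGE_SPLIT < end:
        cuts.add(AGE_SPLIT)
    grid = sorted(cuts)
    for s, e in zip(grid[:-1], grid[1:]):
        yield rates.interval_index(s), s, e - s, int(s >= AGE_SPLIT)


def absolute_risk(profile: RiskProfile, coeffs: CoefficientSet,
                  rates: RateTable, a: Optional[float] = None,
                  h: float = 5.0) -> RiskProjection:
    """Project absolute invasive breast-cancer risk over ``[a, a+h)``.

    Parameters
    ----------
    profile
        Coded risk factors; supplies the relative risks for both age strata.
    coeffs, rates
        Coefficient set (with its AR pair) and age-specific rate table.
    a
        Start age in years; defaults to the profile's entry age.
    h
        Horizon in years (> 0); ``a + h`` may not exceed the table support
        (age 90 for the built-ins).
    """
    if a is None:
        a = profile.entry_age
    if h <= 0:
        raise EngineError(f"horizon must be positive, got {h}")
    if a < 20:
        raise EngineError(f"start age {a} below 20")
    if a + h > rates.support[1]:
        raise EngineError(
            f"projection to age {a + h} exceeds table support {rates.support[1]}")

    r = (relative_risk(profile, coeffs, agecat=0),
         relative_risk(profile, coeffs, agecat=1))
    return _project_with_rr(profile, coeffs, rates, a, h, r)


# --------------------------------------------------------------------------
# Relative-risk grid over the published factor-category combinations
# --------------------------------------------------------------------------

_FLB_LABELS = ("<20", "20-24", "25-29 or nulliparous", ">=30")
_MEN_LABELS = (">=14", "12-13", "<12")
_BMI_LABELS = ("<23.0", "23.0-27.4", ">=27.5")
_PARITY_LABELS = (">=3", "1-2", "0")


def _grid_profile(**codes) -> RiskProfile:
    base = dict(entry_age=55.0, ethnicity="sg-overall", agecat=1, agemen=0,
                ageflb=0, numrel=0, nbiops=0, atypical=None, bmi=0, parity=0)
    base.update(codes)
    if "entry_age" not in codes:  # keep the age consistent with agecat
        base["entry_age"] = 55.0 if base["agecat"] else 45.0
    return RiskProfile(**base)


def rr_table(coeffs: Union[str, CoefficientSet]) -> pd.DataFrame:
    """Relative risks for every factor-category combination of the published
    grid, one block per factor (or factor pair) with the other factors at
    referent level.

    Each row's RR is taken relative to the referent row of its own block, so
    for the biopsy-by-age block the age-category main effect cancels and the
    grid shows the within-stratum biopsy effect.  Columns: ``block``,
    ``category``, the factor codes, ``rr`` (unrounded) and ``rr_2dp``.
    """
    if isinstance(coeffs, str):
        coeffs = builtin_coefficients(coeffs)
    rows = []

    def add(block: str, category: str, ref_codes: dict, **codes):
        prof = _grid_profile(**codes)
        ref = _grid_profile(**ref_codes)
        agecat = codes.get("agecat")
        rr = relative_risk(prof, coeffs, agecat) / relative_risk(ref, coeffs, agecat)
        rows.append({"block": block, "category": category, **codes, "rr": rr,
                     "rr_2dp": round(rr, 2)})

    if "agemen" in coeffs.betas:
        for c, lab in enumerate(_MEN_LABELS):
            add("agemen", lab, {}, agemen=c)
    if "nbiops" in coeffs.betas:
        cap = int(coeffs.code_ranges.get("nbiops", 1))
        for agecat in (0, 1):
            for c in range(cap + 1):
                add("agecat x nbiops", f"{'<50' if agecat == 0 else '>=50'} & {c}",
                    {"agecat": agecat}, agecat=agecat, nbiops=c)
    if "ageflb" in coeffs.betas and "numrel" in coeffs.betas:
        for fc, flab in enumerate(_FLB_LABELS):
            for nc in range(3):
                add("ageflb x numrel", f"{flab} & {nc if nc < 2 else '>=2'}",
                    {}, ageflb=fc, numrel=nc)
    if "bmi" in coeffs.betas:
        for c, lab in enumerate(_BMI_LABELS):
            add("bmi", lab, {}, bmi=c)
    if "parity" in coeffs.betas:
        for c, lab in enumerate(_PARITY_LABELS):
            add("parity", lab, {}, parity=c)
    df = pd.DataFrame(rows)
    code_cols = [c for c in ("agecat", "agemen", "ageflb", "numrel", "nbiops",
                             "bmi", "parity") if c in df.columns]
    df[code_cols] = df[code_cols].fillna(0).astype(int)
    return df


# --------------------------------------------------------------------------
# Cohort prediction
# --------------------------------------------------------------------------

RatesArg = Union[str, RateTable, Mapping[str, RateTable]]


def _resolve_rates(rates: RatesArg, ethnicity: str) -> RateTable:
    if isinstance(rates, RateTable):
        return rates
    if isinstance(rates, str):
        return builtin_rate_table(rates)
    try:
        return rates[ethnicity]
    except KeyError:
        raise EngineError(f"no rate table supplied for ethnicity {ethnicity!r}") from None


def predict_cohort(cohort: pd.DataFrame,
                   coeffs: Union[str, CoefficientSet],
                   rates: RatesArg,
                   horizon: float = 5.0,
                   coded: bool = False) -> pd.DataFrame:
    """Per-woman risk projection over a cohort frame.

    ``rates`` may be a population id, a :class:`RateTable`, or a mapping
    ethnicity -> table (the per-ethnicity analysis). Identical
    (age, ethnicity, relative-risk) combinations are projected once, so
    large cohorts with categorical factors cost only as many projections as
    there are distinct profiles.

    Returns a frame with id, entry_age, r_under50, r_50plus,
    p_breast_cancer, p_other_death, p_event_free (plus case_status when
    present in the input).
    """
    if isinstance(coeffs, str):
        coeffs = builtin_coefficients(coeffs)
    df = cohort if coded else code_cohort(cohort, model=coeffs)
    if len(df) == 0:
        raise EngineError("no rows in cohort")

    lp0, lp1 = _linear_predictors(df, coeffs)
    r0, r1 = np.exp(lp0), np.exp(lp1)
    eth = df["ethnicity"].to_numpy() if "ethnicity" in df else np.repeat("", len(df))
    age = df["entry_age"].to_numpy(float)

    keys = pd.DataFrame({"age": age, "eth": eth, "r0": r0, "r1": r1})
    out = np.empty((len(df), 3), dtype=float)
    for (a, e, rr0, rr1), idx in keys.groupby(["age", "eth", "r0", "r1"],
                                              sort=True).groups.items():
        table = _resolve_rates(rates, e)
        prof = _grid_profile(entry_age=a, agecat=int(a >= AGE_SPLIT), ethnicity=e)
        proj = _project_with_rr(prof, coeffs, table, a, horizon, (rr0, rr1))
        pos = keys.index.get_indexer(idx)
        out[pos] = (proj.p_breast_cancer, proj.p_other_death, proj.p_event_free)

    res = pd.DataFrame({
        "id": df["id"].to_numpy() if "id" in df else np.arange(len(df)).astype(str),
        "entry_age": age,
        "r_under50": r0,
        "r_50plus": r1,
        "p_breast_cancer": out[:, 0],
        "p_other_death": out[:, 1],
        "p_event_free": out[:, 2],
    })
    if "case_status" in df:
        res["case_status"] = df["case_status"].to_numpy()
    return res


def _linear_predictors(coded: pd.DataFrame, coeffs: CoefficientSet):
    """Vectorised beta . x for both age strata over a coded frame."""
    n = len(coded)
    lps = []
    for agecat in (0, 1):
        lp = np.zeros(n)
        for factor, beta in coeffs.betas.items():
            lp += beta * _xcol(coded, factor, agecat, n)
        for (fa, fb), beta in coeffs.interactions:
            lp += beta * _xcol(coded, fa, agecat, n) * _xcol(coded, fb, agecat, n)
        lps.append(lp)
    return lps


def _xcol(coded: pd.DataFrame, factor: str, agecat: int, n: int) -> np.ndarray:
    if factor == "agecat":
        return np.full(n, float(agecat))
    col = coded[factor]
    if str(col.dtype) == "Int64":  # nullable: unknown contributes 0
        return col.fillna(0).to_numpy(float)
    return col.to_numpy(float)


def _project_with_rr(profile: RiskProfile, coeffs: CoefficientSet,
                     rates: RateTable, a: float, h: float,
                     r: tuple[float, float]) -> RiskProjection:
    """absolute_risk with externally supplied stratum relative risks."""
    if h <= 0:
        raise EngineError(f"horizon must be positive, got {h}")
    if a < 20 or a + h > rates.support[1]:
        raise EngineError(f"projection [{a}, {a + h}) outside table support")
    p_bc = p_od = 0.0
    surv = 1.0
    trace = []
    for j, start, delta, agecat in _segments(rates, a, h):
        lam = baseline_hazard(rates, coeffs, j, agecat) * r[agecat]
        mu = rates.other_mortality[j - 1] / 1e5
        trace.append((j, start, delta, lam, mu))
        total = lam + mu
        if total > 0.0:
            mass = surv * -np.expm1(-delta * total)
            p_bc += lam / total * mass
            p_od += mu / total * mass
            surv *= np.exp(-delta * total)
    return RiskProjection(float(p_bc), float(p_od), float(surv), float(a),
                          float(h), r[0], r[1], tuple(trace))
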