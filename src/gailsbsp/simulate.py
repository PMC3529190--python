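"""Synthetic screening-cohort generator and competing-risk outcome simulator.

Profiles are drawn to match the risk-factor prevalences and age/ethnicity
mix observed in the Singapore screening cohort that motivated these models:
menarche-age, BMI and parity category frequencies from the nested
case-control totals, the age-at-first-birth x family-history joint cells as
published, entry ages proportional to the followed age bands (uniform
whole years within a band), and the three-ethnicity mix of the followed
cohort.  Outcomes are then generated from exactly the hazard model the
projection engine assumes — piecewise-exponential cancer and other-death
times with hazards ``b_j * r_i`` and ``c_j`` — so the simulator doubles as
a Monte-Carlo oracle for the projection formula and as a self-consistent
test bed for the calibration machinery.

Parity is sampled conditionally on the age-at-first-birth bucket:
nulliparity is only compatible with the "25-29 or nulliparous" bucket, so
drawing parity = 0 there with probability P(parity 0)/P(bucket) preserves
both published marginals while keeping every record internally consistent.

All randomness flows from one integer seed (or an explicit numpy
Generator); the same seed reproduces the same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import code_cohort
from .engine import AGE_SPLIT, RatesArg, _linear_predictors, _resolve_rates, _segments
from .params import CoefficientSet, RateTable, builtin_coefficients

__all__ = ["SimulationError", "PrevalenceConfig", "sample_profiles",
           "simulate_outcomes", "simulate_cohort"]


class SimulationError(ValueError):
    """Invalid simulation configuration or request."""


def _normalise(counts: Sequence[float]) -> tuple[float, ...]:
    a = np.asarray(counts, dtype=float)
    return tuple(a / a.sum())


@dataclass(frozen=True)
class PrevalenceConfig:
    """Category probabilities for the synthetic cohort.

    Defaults reproduce the published prevalences: probabilities are stored
    as normalised counts so each vector sums to one exactly.  ``ageflb_numrel``
    is the 4 x 3 joint distribution (rows: first-birth buckets <20, 20-24,
    25-29/nulliparous, >=30; columns: 0/1/>=2 affected relatives).
    """

    agemen: tuple[float, ...] = _normalise((1018, 550, 69))
    ageflb_numrel: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in (np.array(
            [[236, 7, 0], [554, 18, 2], [582, 28, 0], [201, 8, 1]], float) / 1637.0)
    )
    bmi: tuple[float, ...] = _normalise((602, 704, 329))  # 2 of 1,637 unknown
    parity: tuple[float, ...] = _normalise((1064, 388, 185))
    p_any_biopsy: float = 1707 / 28883
    ethnicity: tuple[tuple[str, float], ...] = (
        ("sg-chinese", 24339 / 27380), ("sg-malay", 1619 / 27380),
        ("sg-indian", 1422 / 27380))
    age_bands: tuple[tuple[int, int, float], ...] = (
        (45, 49, 109 / 28883), (50, 59, 13911 / 28883),
        (60, 69, 14642 / 28883), (70, 74, 221 / 28883))

    def __post_init__(self) -> None:
        for name, vec in (("agemen", self.agemen), ("bmi", self.bmi),
                          ("parity", self.parity)):
            self._check_probs(name, vec)
        joint = np.asarray(self.ageflb_numrel, dtype=float)
        if joint.shape != (4, 3):
            raise SimulationError("ageflb_numrel must be a 4 x 3 probability table")
        self._check_probs("ageflb_numrel", joint.ravel())
        self._check_probs("ethnicity", [p for _, p in self.ethnicity])
        self._check_probs("age_bands", [p for *_, p in self.age_bands])
        if not (0.0 <= self.p_any_biopsy <= 1.0):
            raise SimulationError("p_any_biopsy must lie in [0, 1]")
        p_flb2 = float(joint[2].sum())
        if self.parity[2] > p_flb2 + 1e-9:
            raise SimulationError(
                "P(parity 0) exceeds P(first-birth bucket '25-29 or nulliparous'); "
                "the two marginals are incompatible")

    @staticmethod
    def _check_probs(name: str, vec) -> None:
        v = np.asarray(list(vec), dtype=float)
        if np.any(v < 0):
            raise SimulationError(f"{name}: negative probability")
        if abs(v.sum() - 1.0) > 1e-9:
            raise SimulationError(f"{name}: probabilities sum to {v.sum()}, not 1")


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# representative raw-value ranges per category code, sampled uniformly
_AGEMEN_RANGES = ((14, 16), (12, 13), (10, 11))
_AGEFLB_RANGES = ((17, 19), (20, 24), (25, 29), (30, 35))
_BMI_RANGES = ((18.0, 22.9), (23.0, 27.4), (27.5, 35.0))
_PARITY_RANGES = ((3, 5), (1, 2))


def sample_profiles(n: int,
                    config: Optional[PrevalenceConfig] = None,
                    seed: Union[int, np.random.Generator, None] = 0) -> pd.DataFrame:
    """Draw ``n`` raw records with the configured prevalences.

    Factors are independent except the age-at-first-birth x family-history
    joint and the parity/nulliparity coupling described in the module
    docstring.  Returns a cohort frame in the raw-record column layout.
    """
    if n < 1:
        raise SimulationError(f"n must be >= 1, got {n}")
    config = config or PrevalenceConfig()
    rng = _rng(seed)

    band_idx = rng.choice(len(config.age_bands), size=n,
                          p=[p for *_, p in config.age_bands])
    lo = np.array([b[0] for b in config.age_bands])[band_idx]
    hi = np.array([b[1] for b in config.age_bands])[band_idx]
    entry_age = rng.integers(lo, hi + 1)  # whole years, uniform in band

    eth = np.array([e for e, _ in config.ethnicity])[
        rng.choice(len(config.ethnicity), size=n, p=[p for _, p in config.ethnicity])]

    agemen_code = rng.choice(3, size=n, p=config.agemen)
    joint = np.asarray(config.ageflb_numrel, dtype=float).ravel()
    cell = rng.choice(12, size=n, p=joint)
    flb_code, numrel_code = np.divmod(cell, 3)

    # parity: nulliparous only inside first-birth bucket 2, preserving marginals
    p_flb2 = float(np.asarray(config.ageflb_numrel)[2].sum())
    p_nullip_given_flb2 = config.parity[2] / p_flb2 if p_flb2 > 0 else 0.0
    nullip = (flb_code == 2) & (rng.random(n) < p_nullip_given_flb2)
    p12 = config.parity[1] / (config.parity[0] + config.parity[1])
    parity_code_pos = np.where(rng.random(n) < p12, 1, 0)  # among parous women

    n_biops = (rng.random(n) < config.p_any_biopsy).astype(int)

    def uniform_int(ranges, codes):
        lo = np.array([r[0] for r in ranges])[codes]
        hi = np.array([r[1] for r in ranges])[codes]
        return rng.integers(lo, hi + 1)

    age_menarche = uniform_int(_AGEMEN_RANGES, agemen_code)
    flb_age = uniform_int(_AGEFLB_RANGES, flb_code).astype(object)
    flb_age[nullip] = "nulliparous"
    bmi_lo = np.array([r[0] for r in _BMI_RANGES])[rng.choice(3, size=n, p=config.bmi)]
    bmi = np.round(bmi_lo + rng.random(n) * 4.0, 1)
    bmi = np.minimum(np.maximum(bmi, 15.0), 45.0)
    parity = np.where(nullip, 0, uniform_int(_PARITY_RANGES, parity_code_pos))

    return pd.DataFrame({
        "id": [f"w{i:06d}" for i in range(n)],
        "entry_age": entry_age.astype(float),
        "ethnicity": eth,
        "age_menarche": age_menarche.astype(float),
        "age_first_live_birth": flb_age,
        "n_first_degree_relatives": numrel_code.astype(float),
        "n_benign_biopsies": n_biops.astype(float),
        "atypical_hyperplasia": [None] * n,
        "bmi": bmi,
        "parity": parity.astype(float),
    })


def simulate_outcomes(profiles: pd.DataFrame,
                      coeffs: Union[str, CoefficientSet],
                      rates: RatesArg,
                      horizon: float = 5.0,
                      seed: Union[int, np.random.Generator, None] = 0,
                      coded: bool = False) -> pd.DataFrame:
    """Draw competing-risk outcomes for each woman over ``horizon`` years.

    Cancer and other-death times are independent piecewise exponentials
    with hazards ``b_j * r_i`` (relative risk and AR switching stratum at
    age 50) and ``c_j``, drawn by inverse transform on the cumulative
    hazard from entry age.  Times beyond the horizon are censored to +inf.
    Returns the input frame plus ``bc_time``, ``death_time`` (years from
    entry) and ``case_status`` (1 iff cancer strikes first, inside the
    horizon).
    """
    if horizon <= 0:
        raise SimulationError(f"horizon must be positive, got {horizon}")
    if isinstance(coeffs, str):
        coeffs = builtin_coefficients(coeffs)
    coded_df = profiles if coded else code_cohort(profiles, model=coeffs)
    n = len(coded_df)
    rng = _rng(seed)

    lp0, lp1 = _linear_predictors(coded_df, coeffs)
    r = np.column_stack([np.exp(lp0), np.exp(lp1)])
    age = coded_df["entry_age"].to_numpy(float)
    eth = coded_df["ethnicity"].to_numpy() if "ethnicity" in coded_df else np.repeat("", n)

    bc_time = np.full(n, np.inf)
    death_time = np.full(n, np.inf)
    e_bc = rng.standard_exponential(n)
    e_od = rng.standard_exponential(n)

    keys = pd.DataFrame({"age": age, "eth": eth})
    for (a, e), idx in keys.groupby(["age", "eth"], sort=True).groups.items():
        table = _resolve_rates(rates, e)
        if a + horizon > table.support[1]:
            raise SimulationError(
                f"horizon reaches age {a + horizon}, beyond table support "
                f"{table.support[1]}")
        segs = list(_segments(table, float(a), float(horizon)))
        pos = keys.index.get_indexer(idx)
        deltas = np.array([s[2] for s in segs])
        mu = np.array([table.other_mortality[s[0] - 1] / 1e5 for s in segs])
        base = np.array([
            table.breast_incidence[s[0] - 1]
            * (1.0 - coeffs.attributable_risk(s[3])) / 1e5 for s in segs])
        agecats = np.array([s[3] for s in segs])
        lam = base[None, :] * r[pos][:, agecats]  # (m, k) cancer hazards
        bc_time[pos] = _invert_piecewise(lam, deltas, e_bc[pos])
        death_time[pos] = _invert_piecewise(
            np.broadcast_to(mu, lam.shape), deltas, e_od[pos])

    out = (profiles if not coded else coded_df).copy()
    out["bc_time"] = bc_time
    out["death_time"] = death_time
    out["case_status"] = ((bc_time < death_time) & (bc_time < horizon)).astype(int)
    return out


def _invert_piecewise(haz: np.ndarray, deltas: np.ndarray,
                      e: np.ndarray) -> np.ndarray:
    """Inverse-transform sample of piecewise-constant-hazard event times.

    ``haz`` is (m, k) per-woman per-segment hazards, ``deltas`` the segment
    widths, ``e`` unit exponentials. Events past the last segment -> +inf.
    """
    cum = np.cumsum(haz * deltas[None, :], axis=1)  # (m, k)
    k = haz.shape[1]
    seg = np.sum(cum < e[:, None], axis=1)  # first segment where cum >= e
    t = np.full(len(e), np.inf)
    inside = seg < k
    prev = np.where(seg > 0, np.take_along_axis(
        cum, np.maximum(seg - 1, 0)[:, None], axis=1).ravel(), 0.0)
    h = np.take_along_axis(haz, np.minimum(seg, k - 1)[:, None], axis=1).ravel()
    starts = np.concatenate([[0.0], np.cumsum(deltas)])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = starts[np.minimum(seg, k - 1)] + (e - prev) / h
    t[inside] = t_in[inside]
    return t


def simulate_cohort(n: int,
                    coeffs: Union[str, CoefficientSet] = "s-gail-sbsp",
                    rates: RatesArg = "sg-overall",
                    horizon: float = 5.0,
                    config: Optional[PrevalenceConfig] = None,
                    seed: Union[int, np.random.Generator, None] = 0) -> pd.DataFrame:
    """Sample ``n`` profiles and their simulated outcomes in one call."""
    rng = _rng(seed)
    profiles = sample_profiles(n, config=config, seed=rng)
    return simulate_outcomes(profiles, coeffs, rates, horizon=horizon, seed=rng)
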