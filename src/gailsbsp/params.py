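"""Parameter registries: age-specific rate tables and model coefficient sets.

Two kinds of parameters drive a Gail-type absolute-risk projection:

* a :class:`RateTable` of age-specific invasive breast-cancer incidence
  ``B_j`` and competing (non-breast-cancer) mortality ``c_j``, on a grid of
  5-year age intervals indexed ``j = 1..15`` with upper bounds
  ``tau_j = 20, 25, ..., 90``;
* a :class:`CoefficientSet` of log-relative-risk coefficients ``beta`` for
  the coded risk factors, any interaction terms, and the pair of
  attributable-risk fractions (AR) used to deflate composite incidence to a
  referent-profile baseline.

Rates are stored exactly as published, per 100,000 woman-years; the
projection engine divides by 100,000 at the point of use.  Built-ins cover
the 1983–87 US Caucasian (SEER/BCDDP) rates and the 2003–07 Singapore rates
(overall and per ethnic group), and the four coefficient sets: the original
BCDDP model and the three Singapore recalibrations (gail-sbsp, s-gail-sbsp,
e-gail-sbsp).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "RateTable",
    "CoefficientSet",
    "RATE_TABLE_IDS",
    "COEFFICIENT_SET_IDS",
    "builtin_rate_table",
    "builtin_coefficients",
    "load_rate_table",
    "save_rate_table",
    "load_coefficients",
    "save_coefficients",
    "export_csv",
]

RATE_FORMAT = "gailsbsp/rate-table/v1"
COEF_FORMAT = "gailsbsp/coefficient-set/v1"


class ParameterError(ValueError):
    """A parameter table violates its schema or an invariant."""


@dataclass(frozen=True)
class RateTable:
    """Piecewise-constant incidence/mortality rates on 5-year age intervals.

    ``upper_bounds[j-1]`` is tau_j, the exclusive upper age of interval j;
    interval 1 spans [0, 20) and the open-ended last interval (>= 85) is
    given nominal width 5, so projections are refused beyond age 90.
    Rates are per 100,000 woman-years, exactly as published.
    """

    population: str
    upper_bounds: tuple[float, ...]
    breast_incidence: tuple[float, ...]  # B_j
    other_mortality: tuple[float, ...]  # c_j

    def __post_init__(self) -> None:
        n = len(self.upper_bounds)
        if n < 1:
            raise ParameterError("rate table needs at least one interval")
        if not (len(self.breast_incidence) == len(self.other_mortality) == n):
            raise ParameterError("intervals, incidence and mortality lengths differ")
        ub = np.asarray(self.upper_bounds, dtype=float)
        if not np.all(np.diff(ub) > 0):
            raise ParameterError("interval upper bounds tau_j must be strictly increasing")
        if np.any(np.asarray(self.breast_incidence) < 0):
            raise ParameterError("breast_incidence: negative B_j")
        if np.any(np.asarray(self.other_mortality) < 0):
            raise ParameterError("other_mortality: negative c_j")

    @property
    def lower_bounds(self) -> tuple[float, ...]:
        return (0.0,) + self.upper_bounds[:-1]

    @property
    def support(self) -> tuple[float, float]:
        """Closed-open age range [0, tau_max) covered by the table."""
        return (0.0, self.upper_bounds[-1])

    def interval_index(self, age: float) -> int:
        """1-based index j of the interval containing ``age``."""
        lo, hi = self.support
        if not (lo <= age < hi):
            raise ParameterError(
                f"age {age} outside table support [{lo}, {hi})"
            )
        j = int(np.searchsorted(np.asarray(self.upper_bounds), age, side="right")) + 1
        return j

    def rates_at(self, age: float) -> tuple[float, float]:
        """(B_j, c_j) per 100,000 woman-years at ``age``."""
        j = self.interval_index(age)
        return self.breast_incidence[j - 1], self.other_mortality[j - 1]


@dataclass(frozen=True)
class CoefficientSet:
    """Log-relative-risk coefficients, interactions, codes and AR pair.

    ``betas`` maps factor name to its per-category-code coefficient;
    ``interactions`` lists ((factor_a, factor_b), coefficient) product
    terms; ``code_ranges`` gives each factor's maximum category code
    (codes run 0..max).  ``ar_under50`` / ``ar_50plus`` are the
    attributable-risk fractions applied below / at-or-above age 50.

    Factors whose value is unknown for a woman (only ``atypical`` can be)
    contribute 0 to the linear predictor.
    """

    model: str
    betas: Mapping[str, float]
    interactions: tuple[tuple[tuple[str, str], float], ...]
    code_ranges: Mapping[str, int]
    ar_under50: float
    ar_50plus: float

    def __post_init__(self) -> None:
        for ar, label in ((self.ar_under50, "ar_under50"), (self.ar_50plus, "ar_50plus")):
            if not (0.0 <= ar < 1.0):
                raise ParameterError(f"{label} must lie in [0, 1), got {ar}")
        known = set(self.betas) | set(self.code_ranges)
        for (fa, fb), _ in self.interactions:
            if fa not in known or fb not in known:
                raise ParameterError(
                    f"interaction ({fa} x {fb}) references a factor absent from betas/code_ranges"
                )
        for f, hi in self.code_ranges.items():
            if not (isinstance(hi, int) and hi >= 0):
                raise ParameterError(f"code range for {f} must be a non-negative int")

    def attributable_risk(self, agecat: int) -> float:
        return self.ar_50plus if agecat else self.ar_under50

    def with_ar(self, ar_under50: float, ar_50plus: float) -> "CoefficientSet":
        """Copy with a different attributable-risk pair (kept overridable
        because the published record does not pin the pair for every model)."""
        return dataclasses.replace(self, ar_under50=ar_under50, ar_50plus=ar_50plus)


# --------------------------------------------------------------------------
# Built-in rate tables: B_j and c_j per 100,000 woman-years on the 15
# intervals 0-19, 20-24, ..., 80-84, >=85 (tau_j = 20, 25, ..., 90).
# --------------------------------------------------------------------------

_TAU = tuple(float(t) for t in range(20, 95, 5))

_RATE_DATA: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    # population: (B_j, c_j)
    "caucasian-1983-87": (
        (0.0, 1.0, 7.6, 26.6, 66.1, 126.5, 186.6, 221.1, 272.1, 334.8,
         392.3, 417.8, 443.9, 442.1, 410.9),
        (0.0, 49.3, 53.1, 62.5, 82.5, 130.7, 218.1, 365.5, 585.2, 943.9,
         1502.8, 2383.9, 3883.2, 6682.8, 14490.8),
    ),
    "sg-overall": (
        (0.3, 1.9, 8.1, 24.8, 57.6, 118.7, 162.6, 187.0, 204.3, 199.1,
         193.9, 166.5, 179.0, 189.8, 166.2),
        (11.7, 14.3, 14.2, 19.8, 32.6, 58.5, 106.2, 182.1, 319.1, 565.9,
         989.5, 1798.6, 3285.3, 5681.0, 11425.5),
    ),
    "sg-chinese": (
        (0.2, 1.8, 7.0, 25.5, 60.3, 121.5, 169.1, 193.6, 211.0, 202.1,
         199.8, 161.3, 180.9, 191.4, 164.5),
        (10.5, 11.9, 12.5, 16.8, 29.4, 51.6, 95.1, 165.1, 271.1, 489.6,
         856.5, 1624.3, 3001.6, 5388.2, 11352.1),
    ),
    "sg-malay": (
        (0.5, 1.1, 15.9, 27.7, 60.0, 123.7, 145.1, 158.4, 167.0, 209.3,
         131.9, 199.1, 128.6, 188.4, 117.6),
        (17.4, 25.7, 22.5, 47.0, 53.9, 98.6, 175.1, 297.5, 617.7, 1093.0,
         2040.3, 3034.6, 5678.6, 8681.2, 13323.5),
    ),
    "sg-indian": (
        (0.5, 2.2, 4.9, 5.9, 31.6, 87.9, 128.4, 147.2, 181.5, 157.6,
         219.5, 152.5, 197.2, 125.0, 375.0),
        (11.0, 12.9, 19.7, 14.8, 34.8, 60.7, 111.9, 212.6, 445.9, 853.3,
         1158.5, 1932.2, 3662.0, 6093.8, 11000.0),
    ),
}

RATE_TABLE_IDS = tuple(_RATE_DATA)

# --------------------------------------------------------------------------
# Built-in coefficient sets.
#
# The BCDDP attributable-risk pair (under 50 / 50 and over) is 0.4771/0.4736;
# the Singapore pair estimated for the extended model is 0.5356/0.5397.
# gail-sbsp and s-gail-sbsp default to the BCDDP pair (the published
# projections are consistent with it); the pair is overridable via
# CoefficientSet.with_ar.
#
# The original BCDDP model carries an atypical-hyperplasia term
# (beta = 0.57405) which contributes 0 whenever the status is unknown; the
# Singapore models exclude the factor entirely (it was unobservable in the
# screening cohort, coded "unknown" throughout).
# --------------------------------------------------------------------------

_AR_BCDDP = (0.4771, 0.4736)
_AR_SG = (0.5356, 0.5397)

_BCDDP_BETAS = {
    "agecat": 0.01081,
    "agemen": 0.09401,
    "ageflb": 0.21863,
    "numrel": 0.95830,
    "nbiops": 0.52926,
    "atypical": 0.57405,
}
_BCDDP_INTERACTIONS = (
    (("nbiops", "agecat"), -0.28804),
    (("ageflb", "numrel"), -0.19081),
)

_COMMON_RANGES = {"agecat": 1, "agemen": 2, "ageflb": 3, "numrel": 2}

_COEF_DATA: dict[str, CoefficientSet] = {
    "bcddp": CoefficientSet(
        model="bcddp",
        betas=dict(_BCDDP_BETAS),
        interactions=_BCDDP_INTERACTIONS,
        code_ranges={**_COMMON_RANGES, "nbiops": 2, "atypical": 1},
        ar_under50=_AR_BCDDP[0],
        ar_50plus=_AR_BCDDP[1],
    ),
    "gail-sbsp": CoefficientSet(
        model="gail-sbsp",
        betas={k: v for k, v in _BCDDP_BETAS.items() if k != "atypical"},
        interactions=_BCDDP_INTERACTIONS,
        code_ranges={**_COMMON_RANGES, "nbiops": 1},
        ar_under50=_AR_BCDDP[0],
        ar_50plus=_AR_BCDDP[1],
    ),
    "s-gail-sbsp": CoefficientSet(
        model="s-gail-sbsp",
        betas={"agemen": 0.238, "ageflb": 0.183, "numrel": 0.777},
        interactions=(),
        code_ranges={"agemen": 2, "ageflb": 3, "numrel": 2},
        ar_under50=_AR_BCDDP[0],
        ar_50plus=_AR_BCDDP[1],
    ),
    "e-gail-sbsp": CoefficientSet(
        model="e-gail-sbsp",
        betas={
            "agemen": 0.204,
            "ageflb": 0.170,
            "numrel": 0.774,
            "bmi": 0.380,
            "parity": 0.203,
        },
        interactions=(),
        code_ranges={"agemen": 2, "ageflb": 3, "numrel": 2, "bmi": 2, "parity": 2},
        ar_under50=_AR_SG[0],
        ar_50plus=_AR_SG[1],
    ),
}

COEFFICIENT_SET_IDS = tuple(_COEF_DATA)


def builtin_rate_table(population: str) -> RateTable:
    """Return one of the published rate tables.

    Parameters
    ----------
    population
        One of ``caucasian-1983-87``, ``sg-overall``, ``sg-chinese``,
        ``sg-malay``, ``sg-indian``.
    """
    try:
        b, c = _RATE_DATA[population]
    except KeyError:
        raise ParameterError(
            f"unknown rate table {population!r}; valid: {', '.join(RATE_TABLE_IDS)}"
        ) from None
    return RateTable(population=population, upper_bounds=_TAU,
                     breast_incidence=b, other_mortality=c)


def builtin_coefficients(model: str) -> CoefficientSet:
    """Return one of the published coefficient sets
    (``bcddp``, ``gail-sbsp``, ``s-gail-sbsp``, ``e-gail-sbsp``)."""
    try:
        return _COEF_DATA[model]
    except KeyError:
        raise ParameterError(
            f"unknown model {model!r}; valid: {', '.join(COEFFICIENT_SET_IDS)}"
        ) from None


# --------------------------------------------------------------------------
# Structured-text (YAML) serialization. Round-trips bit-exactly at the
# printed precision; loaders re-validate every invariant.
# --------------------------------------------------------------------------


def save_rate_table(table: RateTable, path: str | Path) -> None:
    doc = {
        "format": RATE_FORMAT,
        "population": table.population,
        "units": "per 100,000 woman-years",
        "intervals": [
            {"j": j + 1, "upper": table.upper_bounds[j],
             "incidence": table.breast_incidence[j],
             "mortality": table.other_mortality[j]}
            for j in range(len(table.upper_bounds))
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_rate_table(path: str | Path) -> RateTable:
    doc = _load_doc(path, RATE_FORMAT)
    rows = doc.get("intervals")
    if not isinstance(rows, list) or not rows:
        raise ParameterError(f"{path}: missing or empty 'intervals'")
    try:
        rows = sorted(rows, key=lambda r: int(r["j"]))
        ub = tuple(float(r["upper"]) for r in rows)
        b = tuple(float(r["incidence"]) for r in rows)
        c = tuple(float(r["mortality"]) for r in rows)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"{path}: malformed interval row ({exc})") from None
    if [int(r["j"]) for r in rows] != list(range(1, len(rows) + 1)):
        raise ParameterError(f"{path}: interval indices j must run 1..n without gaps")
    return RateTable(population=str(doc.get("population", "user-defined")),
                     upper_bounds=ub, breast_incidence=b, other_mortality=c)


def save_coefficients(coeffs: CoefficientSet, path: str | Path) -> None:
    doc = {
        "format": COEF_FORMAT,
        "model": coeffs.model,
        "ar_under50": coeffs.ar_under50,
        "ar_50plus": coeffs.ar_50plus,
        "betas": dict(coeffs.betas),
        "code_ranges": dict(coeffs.code_ranges),
        "interactions": [
            {"factors": list(pair), "beta": beta} for pair, beta in coeffs.interactions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_coefficients(path: str | Path) -> CoefficientSet:
    doc = _load_doc(path, COEF_FORMAT)
    try:
        betas = {str(k): float(v) for k, v in dict(doc["betas"]).items()}
        ranges = {str(k): int(v) for k, v in dict(doc.get("code_ranges", {})).items()}
        inter = tuple(
            ((str(r["factors"][0]), str(r["factors"][1])), float(r["beta"]))
            for r in doc.get("interactions", [])
        )
        return CoefficientSet(
            model=str(doc.get("model", "user-defined")),
            betas=betas,
            interactions=inter,
            code_ranges=ranges,
            ar_under50=float(doc["ar_under50"]),
            ar_50plus=float(doc["ar_50plus"]),
        )
    except ParameterError:
        raise
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ParameterError(f"{path}: malformed coefficient file ({exc})") from None


def _load_doc(path: str | Path, expected_format: str) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"{path}: not valid YAML ({exc})") from None
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: expected a mapping document")
    if doc.get("format") != expected_format:
        raise ParameterError(
            f"{path}: format header {doc.get('format')!r} != {expected_format!r}"
        )
    return doc


def export_csv(dest: str | Path) -> list[Path]:
    """Write every built-in table/coefficient set as plain CSV for inspection."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pop in RATE_TABLE_IDS:
        t = builtin_rate_table(pop)
        p = dest / f"rates_{pop}.csv"
        with p.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["j", "upper_bound", "breast_incidence_per_100k",
                        "other_mortality_per_100k"])
            for j in range(len(t.upper_bounds)):
                w.writerow([j + 1, t.upper_bounds[j], t.breast_incidence[j],
                            t.other_mortality[j]])
        written.append(p)
    for model in COEFFICIENT_SET_IDS:
        cs = builtin_coefficients(model)
        p = dest / f"coefficients_{model}.csv"
        with p.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "beta"])
            for k, v in cs.betas.items():
                w.writerow([k, v])
            for (fa, fb), v in cs.interactions:
                w.writerow([f"{fa}:{fb}", v])
            w.writerow(["ar_under50", cs.ar_under50])
            w.writerow(["ar_50plus", cs.ar_50plus])
        written.append(p)
    return written
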