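"""Risk-factor coding: raw questionnaire values -> integer category codes.

Category cuts follow the published coding grid: closed on the printed lower
edge (age 50 -> agecat 1, BMI 23.0 -> code 1, 27.5 -> code 2).  Unknown
values map to the referent code and never raise; for age-at-first-live-birth
the referent bucket is the conventional "25-29 or nulliparous" category
(code 2), configurable via ``unknown_ageflb_code``.

Cohorts travel as pandas DataFrames with one row per woman (columns mirror
:class:`RawRecord`; unknowns are empty cells / NA).  :func:`code_cohort`
vectorises the per-woman coders over such a frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import CoefficientSet, builtin_coefficients

__all__ = [
    "CodingError",
    "RawRecord",
    "RiskProfile",
    "UNKNOWN",
    "code_agemen",
    "code_ageflb",
    "code_numrel",
    "code_nbiops",
    "code_bmi",
    "code_parity",
    "code_atypical",
    "make_profile",
    "code_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]


class CodingError(ValueError):
    """Raw value outside its valid domain, or an internally contradictory record."""


#: Sentinel accepted anywhere a raw value may be missing.
UNKNOWN = None

NULLIPAROUS = "nulliparous"


def _is_unknown(x) -> bool:
    if x is None:
        return True
    if isinstance(x, str):
        return x.strip().lower() in {"", "na", "nan", "unknown"}
    try:
        return bool(math.isnan(x))
    except TypeError:
        return False


@dataclass(frozen=True)
class RawRecord:
    """One woman's raw risk-factor questionnaire values.

    ``age_first_live_birth`` may be an age in years, the string
    ``"nulliparous"``, or unknown.  Counts and ages are whole numbers;
    unknowns are ``None``/NaN/"NA".
    """

    id: str
    entry_age: float
    ethnicity: str = "sg-overall"
    age_menarche: Optional[float] = None
    age_first_live_birth: Union[float, str, None] = None
    n_first_degree_relatives: Optional[float] = None
    n_benign_biopsies: Optional[float] = None
    atypical_hyperplasia: Union[str, float, None] = None
    bmi: Optional[float] = None
    parity: Optional[float] = None
    case_status: Optional[int] = None

    def __post_init__(self) -> None:
        if not (20 <= self.entry_age < 85):
            raise CodingError(f"record {self.id}: entry_age {self.entry_age} outside [20, 85)")
        for name in ("n_first_degree_relatives", "n_benign_biopsies", "parity"):
            v = getattr(self, name)
            if not _is_unknown(v) and v < 0:
                raise CodingError(f"record {self.id}: {name} negative ({v})")
        if not _is_unknown(self.bmi) and self.bmi <= 0:
            raise CodingError(f"record {self.id}: non-positive bmi ({self.bmi})")


@dataclass(frozen=True)
class RiskProfile:
    """Fully coded risk factors for one woman, ready for the risk engine."""

    entry_age: float
    ethnicity: str
    agecat: int  # 0 below 50, 1 at 50 or above
    agemen: int
    ageflb: int
    numrel: int
    nbiops: int
    atypical: Optional[int]  # None = unknown (contributes 0)
    bmi: int
    parity: int
    id: str = ""
    case_status: Optional[int] = None

    def __post_init__(self) -> None:
        if self.agecat != int(self.entry_age >= 50):
            raise CodingError(f"agecat {self.agecat} inconsistent with entry_age {self.entry_age}")
        for name, hi in (("agemen", 2), ("ageflb", 3), ("numrel", 2), ("nbiops", 2),
                         ("bmi", 2), ("parity", 2)):
            v = getattr(self, name)
            if not (0 <= v <= hi):
                raise CodingError(f"{name} code {v} outside 0..{hi}")

    def code(self, factor: str, agecat: Optional[int] = None):
        if factor == "agecat":
            return self.agecat if agecat is None else agecat
        return getattr(self, factor)


def code_agemen(age_menarche) -> int:
    """Age at menarche: >=14 -> 0, 12-13 -> 1, <12 -> 2; unknown -> 0."""
    if _is_unknown(age_menarche):
        return 0
    if age_menarche <= 0:
        raise CodingError(f"age_menarche must be positive, got {age_menarche}")
    if age_menarche >= 14:
        return 0
    if age_menarche >= 12:
        return 1
    return 2


def code_ageflb(age_first_live_birth, unknown_code: int = 2) -> int:
    """Age at first live birth: <20 -> 0, 20-24 -> 1, 25-29 or nulliparous
    -> 2, >=30 -> 3; unknown -> ``unknown_code`` (default: the 25-29 /
    nulliparous referent bucket)."""
    v = age_first_live_birth
    if _is_unknown(v):
        return unknown_code
    if isinstance(v, str):
        if v.strip().lower() == NULLIPAROUS:
            return 2
        try:
            v = float(v)
        except ValueError:
            raise CodingError(f"unrecognised age_first_live_birth {v!r}") from None
    if v <= 0:
        raise CodingError(f"age_first_live_birth must be positive, got {v}")
    if v < 20:
        return 0
    if v < 25:
        return 1
    if v < 30:
        return 2
    return 3


def code_numrel(count) -> int:
    """Affected first-degree relatives: 0 -> 0, 1 -> 1, >=2 -> 2; unknown -> 0."""
    if _is_unknown(count):
        return 0
    if count < 0:
        raise CodingError(f"relative count negative: {count}")
    return min(int(count), 2)


def code_nbiops(count, model: Union[str, CoefficientSet] = "gail-sbsp") -> int:
    """Benign breast biopsies. The original BCDDP model distinguishes
    0 / 1 / >=2; the Singapore models collapse any biopsy history to a
    single-biopsy code (0 / >=1 -> 1). Unknown -> 0."""
    if _is_unknown(count):
        return 0
    if count < 0:
        raise CodingError(f"biopsy count negative: {count}")
    cap = _nbiops_cap(model)
    return min(int(count), cap)


def _nbiops_cap(model: Union[str, CoefficientSet]) -> int:
    if isinstance(model, CoefficientSet):
        return int(model.code_ranges.get("nbiops", 1))
    return 2 if model == "bcddp" else 1


def code_bmi(bmi) -> int:
    """Body-mass index on the WHO Asian cuts: <23.0 -> 0, 23.0-27.4 -> 1,
    >=27.5 -> 2; unknown -> 0."""
    if _is_unknown(bmi):
        return 0
    if bmi <= 0:
        raise CodingError(f"bmi must be positive, got {bmi}")
    if bmi < 23.0:
        return 0
    if bmi < 27.5:
        return 1
    return 2


def code_parity(count) -> int:
    """Live births: >=3 -> 0 (referent), 1-2 -> 1, 0 -> 2; unknown -> 0."""
    if _is_unknown(count):
        return 0
    if count < 0:
        raise CodingError(f"parity negative: {count}")
    n = int(count)
    if n >= 3:
        return 0
    if n >= 1:
        return 1
    return 2


def code_atypical(value) -> Optional[int]:
    """Atypical hyperplasia: no -> 0, yes -> 1, unknown -> None (the
    coefficient is skipped; historically coded 99)."""
    if _is_unknown(value):
        return None
    if isinstance(value, str):
        s = value.strip().lower()
        if s in {"no", "n", "0"}:
            return 0
        if s in {"yes", "y", "1"}:
            return 1
        raise CodingError(f"unrecognised atypical_hyperplasia {value!r}")
    if int(value) == 99:
        return None
    if value in (0, 1):
        return int(value)
    raise CodingError(f"unrecognised atypical_hyperplasia {value!r}")


def make_profile(record: RawRecord,
                 model: Union[str, CoefficientSet] = "gail-sbsp",
                 unknown_ageflb_code: int = 2) -> RiskProfile:
    """Code a raw record into a :class:`RiskProfile`.

    Rejects internally contradictory records: a nulliparous woman with
    parity > 0, or a recorded age-at-first-live-birth alongside parity 0.
    """
    flb = record.age_first_live_birth
    nullip = isinstance(flb, str) and flb.strip().lower() == NULLIPAROUS
    if not _is_unknown(record.parity):
        if nullip and record.parity > 0:
            raise CodingError(
                f"record {record.id}: nulliparous but parity {record.parity}")
        if record.parity == 0 and not nullip and not _is_unknown(flb):
            raise CodingError(
                f"record {record.id}: age_first_live_birth {flb} recorded with parity 0")
    return RiskProfile(
        entry_age=record.entry_age,
        ethnicity=record.ethnicity,
        agecat=int(record.entry_age >= 50),
        agemen=code_agemen(record.age_menarche),
        ageflb=code_ageflb(flb, unknown_code=unknown_ageflb_code),
        numrel=code_numrel(record.n_first_degree_relatives),
        nbiops=code_nbiops(record.n_benign_biopsies, model),
        atypical=code_atypical(record.atypical_hyperplasia),
        bmi=code_bmi(record.bmi),
        parity=code_parity(record.parity),
        id=record.id,
        case_status=None if _is_unknown(record.case_status) else int(record.case_status),
    )


# --------------------------------------------------------------------------
# Cohort (DataFrame) interface
# --------------------------------------------------------------------------

COHORT_COLUMNS = (
    "id", "entry_age", "ethnicity", "age_menarche", "age_first_live_birth",
    "n_first_degree_relatives", "n_benign_biopsies", "atypical_hyperplasia",
    "bmi", "parity", "case_status",
)


def code_cohort(df: pd.DataFrame,
                model: Union[str, CoefficientSet] = "gail-sbsp",
                unknown_ageflb_code: int = 2) -> pd.DataFrame:
    """Vectorised :func:`make_profile` over a cohort frame.

    Returns a frame with columns id, entry_age, ethnicity, case_status and
    the integer codes agecat/agemen/ageflb/numrel/nbiops/bmi/parity plus
    atypical (nullable). Raises :class:`CodingError` naming the first
    offending row on invalid input.
    """
    if "entry_age" not in df.columns:
        raise CodingError("cohort frame lacks an entry_age column")
    n = len(df)
    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"].astype(str) if "id" in df else np.arange(n).astype(str)
    age = pd.to_numeric(df["entry_age"], errors="raise").to_numpy(float)
    bad = ~((age >= 20) & (age < 85))
    if bad.any():
        i = df.index[bad][0]
        raise CodingError(f"row {out['id'][i]}: entry_age {age[np.flatnonzero(bad)[0]]} outside [20, 85)")
    out["entry_age"] = age
    out["ethnicity"] = df["ethnicity"].astype(str) if "ethnicity" in df else "sg-overall"
    out["agecat"] = (age >= 50).astype(int)

    def col(name):
        return df[name] if name in df else pd.Series([None] * n, index=df.index)

    out["agemen"] = [code_agemen(v) for v in col("age_menarche")]
    out["ageflb"] = [code_ageflb(v, unknown_code=unknown_ageflb_code)
                     for v in col("age_first_live_birth")]
    out["numrel"] = [code_numrel(v) for v in col("n_first_degree_relatives")]
    out["nbiops"] = [code_nbiops(v, model) for v in col("n_benign_biopsies")]
    out["atypical"] = pd.array([code_atypical(v) for v in col("atypical_hyperplasia")],
                               dtype="Int64")
    out["bmi"] = [code_bmi(v) for v in col("bmi")]
    out["parity"] = [code_parity(v) for v in col("parity")]
    if "case_status" in df:
        out["case_status"] = pd.to_numeric(df["case_status"], errors="coerce").astype("Int64")
    else:
        out["case_status"] = pd.array([pd.NA] * n, dtype="Int64")

    nullip = col("age_first_live_birth").astype(str).str.strip().str.lower() == NULLIPAROUS
    par = pd.to_numeric(col("parity"), errors="coerce")
    conflict = nullip & (par > 0)
    if conflict.any():
        i = df.index[conflict][0]
        raise CodingError(f"row {out['id'][i]}: nulliparous but parity {par[i]}")
    conflict = (par == 0) & ~nullip & col("age_first_live_birth").notna() & ~nullip
    if conflict.any():
        i = df.index[conflict][0]
        raise CodingError(f"row {out['id'][i]}: age_first_live_birth recorded with parity 0")
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (one row per woman; unknowns empty or "NA")."""
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True,
                     comment="#", dtype={"age_first_live_birth": object})
    if len(df) == 0:
        raise CodingError(f"{path}: no rows")
    missing = {"entry_age"} - set(df.columns)
    if missing:
        raise CodingError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)
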