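"""Model validation: expected/observed calibration and concordance.

Calibration compares the expected case count E (the sum of predicted
5-year risks over a group) with the observed count O.  The E/O ratio
carries a log-scale 95% interval (E/O) * exp(+-1.96 * sqrt(1/O)), and the
overall fit over k groups uses sum((O - E)^2 / E) referred to a chi-square
distribution with k degrees of freedom.  Note the deliberate use of k (not
k - 1) degrees of freedom, and of df = 1 for a single pooled group: both
follow the published methodology for these models rather than the more
common Pearson convention.

Discrimination uses the concordance probability (AUC): the rank-based
Mann-Whitney estimate with midranks for ties, which is invariant to any
strictly monotone transform of the predicted risks (so computing it on raw
risks is equivalent to first fitting a logistic model on them).  Cohort
discrimination is summarised as an average of age-group-specific AUCs
weighted by group size, with variance sum(w^2 * var); age groups without a
case (or without a control) carry no information about concordance and are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .coding import code_cohort
from .engine import RatesArg, predict_cohort
from .params import CoefficientSet, builtin_coefficients

__all__ = [
    "ValidationError",
    "CalibrationReport",
    "ConcordanceReport",
    "expected_cases",
    "eo_ratio_ci",
    "goodness_of_fit",
    "group_calibration",
    "auc",
    "weighted_concordance",
    "decile_calibration",
    "parse_age_bands",
]

Z95 = 1.96  # fixed as published, not a normal quantile call


class ValidationError(ValueError):
    """Invalid validation input (risks out of range, degenerate groups...)."""


@dataclass(frozen=True)
class CalibrationReport:
    """Per-group observed/expected rows plus the overall chi-square fit."""

    rows: pd.DataFrame  # group, n_women, observed, expected, eo_ratio, ci_lower, ci_upper
    chi2: float
    df: int
    p_value: float

    def __str__(self) -> str:  # human-readable summary
        lines = [self.rows.to_string(index=False),
                 f"goodness of fit: chi2 = {self.chi2:.4f} on {self.df} df, "
                 f"P = {self.p_value:.4g}"]
        return "\n".join(lines)


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-age-band AUCs and their size-weighted average."""

    rows: pd.DataFrame  # band, n_women, cases, auc, variance, weight
    auc: float
    variance: float
    ci_lower: float
    ci_upper: float

    def __str__(self) -> str:
        return (self.rows.to_string(index=False)
                + f"\nweighted AUC = {self.auc:.4f} "
                f"(95% CI {self.ci_lower:.4f} to {self.ci_upper:.4f})")


def expected_cases(predicted_risks: Sequence[float]) -> float:
    """E = sum of predicted per-woman risks."""
    r = np.asarray(list(predicted_risks), dtype=float)
    if r.size and (np.any(r < 0) or np.any(r > 1)):
        raise ValidationError("predicted risks must lie in [0, 1]")
    return float(r.sum())


def eo_ratio_ci(E: float, O: int, level: float = 0.95):
    """Expected/observed ratio with its log-scale confidence interval.

    Returns ``(ratio, lower, upper)``; all three are NaN when O = 0 (the
    published tables print a dash there).
    """
    if E < 0:
        raise ValidationError(f"E must be non-negative, got {E}")
    if O < 0 or O != int(O):
        raise ValidationError(f"O must be a non-negative integer, got {O}")
    if O == 0:
        return (float("nan"), float("nan"), float("nan"))
    z = Z95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    ratio = E / O
    half = z * np.sqrt(1.0 / O)
    return (ratio, ratio * np.exp(-half), ratio * np.exp(half))


def goodness_of_fit(observed: Sequence[float], expected: Sequence[float]):
    """Chi-square fit statistic sum((O-E)^2/E) on k = len(observed) df.

    Returns ``(chi2, df, p)``. Every E must be positive (merge sparse
    categories upstream).
    """
    O = np.asarray(list(observed), dtype=float)
    E = np.asarray(list(expected), dtype=float)
    if O.size == 0 or O.shape != E.shape:
        raise ValidationError("observed and expected must be equal-length, non-empty")
    if np.any(E <= 0):
        raise ValidationError("all expected counts must be > 0 (merge empty categories)")
    chi2 = float(np.sum((O - E) ** 2 / E))
    df = int(O.size)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# --------------------------------------------------------------------------
# Cohort-level calibration
# --------------------------------------------------------------------------

_FACTOR_LABELS: Mapping[str, Sequence[str]] = {
    "agemen": (">=14", "12-13", "<12"),
    "ageflb": ("<20", "20-24", "25-29 or nulliparous", ">=30"),
    "numrel": ("0", "1", ">=2"),
    "nbiops": ("0", "1", ">=2"),
    "bmi": ("<23.0", "23.0-27.4", ">=27.5"),
    "parity": (">=3", "1-2", "0"),
}


def parse_age_bands(spec: str) -> list[tuple[int, int]]:
    """Parse e.g. ``"45-49,50-59,60-69,70-74"`` into (lo, hi) inclusive bands."""
    bands = []
    for part in spec.split(","):
        lo, _, hi = part.strip().partition("-")
        bands.append((int(lo), int(hi or lo)))
    return bands


def _band_labels(ages: np.ndarray, bands: Sequence[tuple[int, int]]) -> pd.Series:
    lab = pd.Series([None] * len(ages), dtype=object)
    for lo, hi in bands:
        lab[(ages >= lo) & (ages < hi + 1)] = f"{lo}-{hi}"
    if lab.isna().any():
        raise ValidationError("age bands do not cover every woman in the cohort")
    order = [f"{lo}-{hi}" for lo, hi in bands]
    return pd.Categorical(lab, categories=order, ordered=True)


def group_calibration(cohort: pd.DataFrame,
                      coeffs: Union[str, CoefficientSet],
                      rates: RatesArg,
                      group_by: str = "age-band",
                      age_bands: Sequence[tuple[int, int]] = ((45, 49), (50, 59), (60, 69), (70, 74)),
                      horizon: float = 5.0,
                      coded: bool = False) -> CalibrationReport:
    """Observed vs expected cases per group, with the overall chi-square fit.

    ``group_by`` is ``"age-band"``, ``"ethnicity"``, or one of the coded
    factors (agemen, ageflb, numrel, nbiops, bmi, parity).  Every woman
    needs a 0/1 ``case_status``.  Empty groups are dropped; the chi-square
    runs over groups with E > 0.
    """
    if isinstance(coeffs, str):
        coeffs = builtin_coefficients(coeffs)
    coded_df = cohort if coded else code_cohort(cohort, model=coeffs)
    if coded_df["case_status"].isna().any():
        raise ValidationError("every woman needs a 0/1 case_status for calibration")
    pred = predict_cohort(coded_df, coeffs, rates, horizon=horizon, coded=True)
    status = coded_df["case_status"].to_numpy(int)

    if group_by == "age-band":
        labels = _band_labels(coded_df["entry_age"].to_numpy(float), age_bands)
    elif group_by == "ethnicity":
        labels = coded_df["ethnicity"].to_numpy()
    elif group_by in _FACTOR_LABELS:
        names = _FACTOR_LABELS[group_by]
        codes = coded_df[group_by].fillna(0).to_numpy(int)
        labels = pd.Categorical([names[c] for c in codes], categories=names, ordered=True)
    else:
        raise ValidationError(f"unknown grouping {group_by!r}")

    frame = pd.DataFrame({"group": labels, "risk": pred["p_breast_cancer"].to_numpy(),
                          "status": status})
    rows = []
    for g, sub in frame.groupby("group", observed=True, sort=True):
        if len(sub) == 0:
            continue
        E = expected_cases(sub["risk"])
        O = int(sub["status"].sum())
        ratio, lo, hi = eo_ratio_ci(E, O)
        rows.append({"group": str(g), "n_women": len(sub), "observed": O,
                     "expected": E, "eo_ratio": ratio, "ci_lower": lo, "ci_upper": hi})
    table = pd.DataFrame(rows)
    fit = table[table["expected"] > 0]
    chi2, df, p = goodness_of_fit(fit["observed"], fit["expected"])
    return CalibrationReport(rows=table, chi2=chi2, df=df, p_value=p)


# --------------------------------------------------------------------------
# Discrimination
# --------------------------------------------------------------------------


def auc(predicted: Sequence[float], status: Sequence[int],
        variance: str = "hanley-mcneil") -> tuple[float, float]:
    """Concordance probability and its variance.

    Rank-based (Mann-Whitney) AUC with midranks for ties.  ``variance`` is
    ``"hanley-mcneil"`` (default) or ``"delong"``.
    """
    y = np.asarray(list(status), dtype=int)
    x = np.asarray(list(predicted), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("predicted and status must be equal-length vectors")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValidationError("need at least one case and one non-case")
    ranks = stats.rankdata(x)  # midranks
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    if variance == "hanley-mcneil":
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    elif variance == "delong":
        cases, controls = x[y == 1], x[y == 0]
        v10 = np.array([(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n0
                        for c in cases])
        v01 = np.array([(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / n1
                        for c in controls])
        var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + \
              (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    else:
        raise ValidationError(f"unknown variance estimator {variance!r}")
    return float(a), float(var)


def weighted_concordance(cohort: pd.DataFrame,
                         coeffs: Union[str, CoefficientSet],
                         rates: RatesArg,
                         age_bands: Sequence[tuple[int, int]] = ((45, 49), (50, 59), (60, 69), (70, 74)),
                         horizon: float = 5.0,
                         coded: bool = False,
                         variance: str = "hanley-mcneil") -> ConcordanceReport:
    """Size-weighted average of age-band-specific AUCs.

    Bands without both a case and a control are excluded; weights are
    proportional to band size, renormalised over the included bands;
    variance is sum(weight^2 * band variance) and the 95% interval is
    truncated to [0, 1].
    """
    if isinstance(coeffs, str):
        coeffs = builtin_coefficients(coeffs)
    coded_df = cohort if coded else code_cohort(cohort, model=coeffs)
    if coded_df["case_status"].isna().any():
        raise ValidationError("every woman needs a 0/1 case_status for concordance")
    pred = predict_cohort(coded_df, coeffs, rates, horizon=horizon, coded=True)
    labels = _band_labels(coded_df["entry_age"].to_numpy(float), age_bands)
    frame = pd.DataFrame({"band": labels, "risk": pred["p_breast_cancer"].to_numpy(),
                          "status": coded_df["case_status"].to_numpy(int)})
    rows = []
    for band, sub in frame.groupby("band", observed=True, sort=True):
        n = len(sub)
        cases = int(sub["status"].sum())
        if n == 0 or cases == 0 or cases == n:
            continue  # no concordance information in this band
        a, v = auc(sub["risk"], sub["status"], variance=variance)
        rows.append({"band": str(band), "n_women": n, "cases": cases,
                     "auc": a, "variance": v})
    if not rows:
        raise ValidationError("no age band contains both a case and a non-case")
    table = pd.DataFrame(rows)
    w = table["n_women"].to_numpy(float)
    w = w / w.sum()
    table["weight"] = w
    est = float(np.sum(w * table["auc"]))
    var = float(np.sum(w ** 2 * table["variance"]))
    half = Z95 * np.sqrt(var)
    return ConcordanceReport(rows=table, auc=est, variance=var,
                             ci_lower=max(0.0, est - half),
                             ci_upper=min(1.0, est + half))


def decile_calibration(predicted: Sequence[float], status: Sequence[int]) -> pd.DataFrame:
    """Observed vs mean predicted risk within deciles of predicted risk.

    Deciles are near-equal-size buckets of the risk-sorted cohort (stable
    order for ties; when n is not a multiple of 10 the lower deciles take
    the extra women). Returns columns decile (1 = lowest risk), n,
    mean_predicted, observed_rate, observed_cases.
    """
    x = np.asarray(list(predicted), dtype=float)
    y = np.asarray(list(status), dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("predicted and status must be equal-length vectors")
    if len(x) < 10:
        raise ValidationError("need at least 10 women for a decile split")
    order = np.argsort(x, kind="stable")
    rows = []
    for d, idx in enumerate(np.array_split(order, 10), start=1):
        rows.append({"decile": d, "n": len(idx),
                     "mean_predicted": float(x[idx].mean()),
                     "observed_rate": float(y[idx].mean()),
                     "observed_cases": int(y[idx].sum())})
    return pd.DataFrame(rows)
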