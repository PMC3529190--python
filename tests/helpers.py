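"""Independent oracles and small builders shared across the test suite.

Everything here deliberately avoids the package's own computational paths:
the quadrature oracle integrates the cause-specific density numerically,
the AUC oracle counts case/control pairs exhaustively, and the coded-frame
builder assembles frames by hand.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from gailsbsp import CoefficientSet, RateTable, RiskProfile


def make_profile(entry_age=55.0, ethnicity="sg-overall", agemen=0, ageflb=0,
                 numrel=0, nbiops=0, atypical=None, bmi=0, parity=0,
                 id="", case_status=None) -> RiskProfile:
    return RiskProfile(entry_age=entry_age, ethnicity=ethnicity,
                       agecat=int(entry_age >= 50), agemen=agemen,
                       ageflb=ageflb, numrel=numrel, nbiops=nbiops,
                       atypical=atypical, bmi=bmi, parity=parity,
                       id=id, case_status=case_status)


def coded_frame(n: int, entry_age=55.0, ethnicity="sg-overall", agemen=0,
                ageflb=0, numrel=0, nbiops=0, bmi=0, parity=0) -> pd.DataFrame:
    """A coded cohort frame of n identical women (atypical unknown)."""
    return pd.DataFrame({
        "id": [f"p{i}" for i in range(n)],
        "entry_age": np.full(n, float(entry_age)),
        "ethnicity": [ethnicity] * n,
        "agecat": np.full(n, int(entry_age >= 50)),
        "agemen": np.full(n, agemen), "ageflb": np.full(n, ageflb),
        "numrel": np.full(n, numrel), "nbiops": np.full(n, nbiops),
        "atypical": pd.array([None] * n, dtype="Int64"),
        "bmi": np.full(n, bmi), "parity": np.full(n, parity),
        "case_status": pd.array([None] * n, dtype="Int64"),
    })


def hazard_segments(rates: RateTable, coeffs: CoefficientSet,
                    r_under50: float, r_50plus: float, a: float, h: float):
    """Independent segmentation of [a, a+h): list of (width, lam, mu)."""
    cuts = sorted({a, a + h, 50.0, *[float(t) for t in rates.upper_bounds]})
    cuts = [t for t in cuts if a <= t <= a + h]
    segs = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        j = next(k for k, ub in enumerate(rates.upper_bounds) if s < ub)
        under50 = s < 50.0
        ar = coeffs.ar_under50 if under50 else coeffs.ar_50plus
        r = r_under50 if under50 else r_50plus
        lam = rates.breast_incidence[j] / 1e5 * (1.0 - ar) * r
        mu = rates.other_mortality[j] / 1e5
        segs.append((e - s, lam, mu))
    return segs


def integrate_cause_specific(segs, step: float = 1e-4) -> float:
    """Midpoint-rule integral of the breast-cancer cause-specific density
    lam(t) * exp(-cumulative total hazard) over the segments."""
    p = 0.0
    H = 0.0  # total cumulative hazard to segment start
    for width, lam, mu in segs:
        m = max(1, math.ceil(width / step))
        dt = width / m
        t = (np.arange(m) + 0.5) * dt
        p += float(np.sum(lam * np.exp(-(H + (lam + mu) * t)) * dt))
        H += (lam + mu) * width
    return p


def auc_by_pair_counting(predicted, status) -> float:
    """Exhaustive concordant-pair fraction (ties count half)."""
    x = np.asarray(predicted, float)
    y = np.asarray(status, int)
    cases = x[y == 1]
    controls = x[y == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / (len(cases) * len(controls))
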