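"""Population ovarian-aging curve and endocrine age.

The fraction of women whose predicted POR probability exceeds a threshold
``tau`` (default 0.15, the cohort POR incidence) rises with age along an
S-shaped trajectory.  A two-parameter logistic

    curve(age) = 1 / (1 + exp(-k * (age - x0)))

is fitted to the per-age predicted-DOR proportions by least squares on the
proportion scale; the asymptotes are fixed at 0 and 1.  ``x0`` is the
midpoint age (curve = 0.5) and ``k`` the steepness per year.  Inverting the
curve maps an individual's predicted probability to an "endocrine age" —
the age at which the population curve reaches that probability.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CurveFitError, InsufficientDataError, OutOfRangeError
from .por_models import FittedPorModel, predict_por_probabilities
from .records import CohortRecord

logger = logging.getLogger(__name__)

#: Default predicted-DOR threshold: the cohort POR incidence rate.
DEFAULT_TAU = 0.15
#: Minimum records per integer-age row retained for curve fitting.
DEFAULT_MIN_N = 20
#: Probability clamp bounds for curve inversion.
CLAMP_EPS = 1e-6
#: Deterministic optimizer start for the steepness (per year).
K_START = 0.25


@dataclass(frozen=True)
class DorByAgeTable:
    """Per-integer-age predicted-DOR proportions.

    ``table`` columns: age, n, n_dor, proportion.  ``excluded_ages`` lists
    integer ages dropped for having fewer than ``min_n`` records.
    """

    table: pd.DataFrame
    tau: float
    min_n: int
    excluded_ages: tuple[int, ...] = ()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class AgingCurve:
    """Fitted two-parameter logistic aging curve."""

    k: float
    x0: float
    r_squared: float
    age_domain: tuple[float, float]
    tau: float = DEFAULT_TAU

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "x0": self.x0,
            "r_squared": self.r_squared,
            "age_domain": list(self.age_domain),
            "tau": self.tau,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "AgingCurve":
        return cls(
            k=float(d["k"]),
            x0=float(d["x0"]),
            r_squared=float(d["r_squared"]),
            age_domain=tuple(d["age_domain"]),
            tau=float(d.get("tau", DEFAULT_TAU)),
        )

    @classmethod
    def from_json(cls, text: str) -> "AgingCurve":
        return cls.from_dict(json.loads(text))


def dor_proportions_by_age(
    cohort: Sequence[CohortRecord],
    model: FittedPorModel,
    tau: float = DEFAULT_TAU,
    min_n: int = DEFAULT_MIN_N,
) -> DorByAgeTable:
    """Tabulate the fraction of predicted-DOR women per integer age.

    Ages are floored to integer years.  A record counts as predicted DOR
    when its predicted POR probability is at least ``tau``.  Sparse rows
    (n < ``min_n``) are excluded from the table and listed in
    ``excluded_ages`` — the age extremes of an ART cohort are thin and
    noisy.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("cohort is empty")
    probs = predict_por_probabilities(model, cohort)
    ages = np.floor([r.age_years for r in cohort]).astype(int)
    dor = probs >= tau

    rows, excluded = [], []
    for age in np.unique(ages):
        mask = ages == age
        n = int(mask.sum())
        if n < min_n:
            excluded.append(int(age))
            continue
        n_dor = int(dor[mask].sum())
        rows.append({"age": int(age), "n": n, "n_dor": n_dor, "proportion": n_dor / n})
    if not rows:
        raise InsufficientDataError(
            f"no age row reaches min_n={min_n}; cannot build the DOR-by-age table"
        )
    table = pd.DataFrame(rows, columns=["age", "n", "n_dor", "proportion"])
    return DorByAgeTable(table=table, tau=tau, min_n=min_n, excluded_ages=tuple(excluded))


def _logistic(age, k, x0):
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(age, dtype=float) - x0)))


def _start_x0(ages: np.ndarray, props: np.ndarray) -> float:
    """Age at which the proportion first crosses 0.5, linearly interpolated."""
    above = props >= 0.5
    if above.all() or not above.any():
        return float(ages.mean())
    i = int(np.argmax(above))
    if i == 0:
        return float(ages[0])
    a0, a1 = ages[i - 1], ages[i]
    p0, p1 = props[i - 1], props[i]
    if p1 == p0:
        return float(a1)
    return float(a0 + (0.5 - p0) * (a1 - a0) / (p1 - p0))


def fit_logistic_curve(table: DorByAgeTable, weighting: str = "none") -> AgingCurve:
    """Least-squares fit of the two-parameter logistic to a DOR-by-age table.

    Residuals are on the proportion scale; ``weighting="by_n"`` multiplies
    each squared residual by the row count.  r-squared is
    ``1 - SSres/SStot`` under the same weights.  The start point is
    deterministic (k = 0.25/yr; x0 at the interpolated 0.5 crossing), so
    the fit is reproducible.
    """
    df = table.table
    ages = df["age"].to_numpy(dtype=float)
    props = df["proportion"].to_numpy(dtype=float)
    if ages.size < 4:
        raise InsufficientDataError("need at least 4 age rows to fit the curve")
    if props.min() >= 0.5 or props.max() < 0.5:
        warnings.warn(
            "proportions do not straddle 0.5; the midpoint x0 is extrapolated",
            stacklevel=2,
        )
    if weighting == "by_n":
        w = df["n"].to_numpy(dtype=float)
    elif weighting == "none":
        w = np.ones_like(props)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sw = np.sqrt(w)

    def residuals(theta):
        k, x0 = theta
        return sw * (props - _logistic(ages, k, x0))

    start = np.array([K_START, _start_x0(ages, props)])
    result = least_squares(residuals, start, xtol=1e-10, ftol=1e-10, gtol=1e-10)
    k, x0 = (float(v) for v in result.x)
    if not result.success and abs(k) > 1e-3:
        raise CurveFitError(
            f"logistic curve fit did not converge: {result.message}",
            last_iterate=tuple(result.x),
        )
    if k <= 1e-3:
        # flat or decreasing data: k -> 0 leaves x0 unidentified
        warnings.warn(
            f"fitted steepness k={k:.3g} is not positive; the data are not an "
            "increasing sigmoid and the midpoint is unidentified",
            stacklevel=2,
        )

    ss_res = float(np.sum(w * (props - _logistic(ages, k, x0)) ** 2))
    mean_w = float(np.sum(w * props) / np.sum(w))
    ss_tot = float(np.sum(w * (props - mean_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return AgingCurve(
        k=k,
        x0=x0,
        r_squared=r2,
        age_domain=(float(ages.min()), float(ages.max())),
        tau=table.tau,
    )


def curve_probability(curve: AgingCurve, age: float) -> float:
    """Population predicted-DOR probability at a chronological age."""
    return float(_logistic(age, curve.k, curve.x0))


def endocrine_age(curve: AgingCurve, p: float) -> float:
    """Invert the aging curve: the age at which it reaches probability ``p``.

    ``p`` is clamped to [1e-6, 1 - 1e-6] (clamping is logged): women on the
    young high-reserve plateau produce probabilities numerically at the
    asymptote where the inverse is unbounded.
    """
    if not 0.0 <= p <= 1.0:
        raise OutOfRangeError(f"probability {p} outside [0, 1]")
    clamped = min(max(p, CLAMP_EPS), 1.0 - CLAMP_EPS)
    if clamped != p:
        logger.info("endocrine_age: probability %.3g clamped to %.3g", p, clamped)
    return float(curve.x0 + np.log(clamped / (1.0 - clamped)) / curve.k)
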