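"""Logistic models of poor ovarian response (POR) from AMH and age.

Three nested specifications of the linear predictor are supported:

* ``model0`` — the legacy categorical form: age and AMH are cut into ordered
  bins and entered as indicator columns (reference bin dropped).  The
  original cut-points are not public, so by default quintile bins are
  computed on the training cohort.
* ``model1`` — age and AMH untransformed: logit(p) = b0 + b1*age + b2*AMH.
* ``model2`` — hierarchical polynomial: quadratic in age, cubic in AMH,
  with all lower-order terms retained:
  logit(p) = b0 + b1*age + b2*age^2 + b3*AMH + b4*AMH^2 + b5*AMH^3.

Fitting maximizes the Bernoulli log-likelihood
``sum(y*log p + (1-y)*log(1-p))`` by Newton iteration (iteratively
reweighted least squares).  Optional centering of age and AMH before the
powers conditions the cubic design; fitted probabilities are invariant to
that choice on well-conditioned data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    ConfigError,
    DegenerateDesignError,
    DegenerateFitError,
    InvalidRecordError,
)
from .records import CohortRecord, outcome_subset

MODEL_NAMES = ("model0", "model1", "model2")

#: Default centering constants: a mid-reproductive reference point.
DEFAULT_CENTER_AGE = 35.0
DEFAULT_CENTER_AMH = 2.0

#: Minimum recommended fitting-cohort size; smaller cohorts fit with a warning.
MIN_FIT_N = 50

#: Margin (logit units) by which the fitted linear predictor must split the
#: outcome classes before the fit is flagged as separated.  Complete or
#: quasi-complete separation means some direction classifies the sample
#: perfectly, so the MLE is unbounded; at the returned iterate this shows
#: up as min(eta | event) exceeding max(eta | non-event).
SEPARATION_MARGIN = 0.0


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the POR linear predictor.

    ``age_bins`` / ``amh_bins`` are strictly increasing interior cut-points
    and apply to ``model0`` only; ``m`` cut-points define ``m + 1`` ordered
    bins, the lowest being the reference.  ``center`` subtracts
    ``center_age`` / ``center_amh`` before the polynomial powers
    (``model1``/``model2``).
    """

    name: str
    age_bins: tuple[float, ...] | None = None
    amh_bins: tuple[float, ...] | None = None
    center: bool = False
    center_age: float = DEFAULT_CENTER_AGE
    center_amh: float = DEFAULT_CENTER_AMH

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model name {self.name!r}; expected one of {MODEL_NAMES}")
        for label, bins in (("age_bins", self.age_bins), ("amh_bins", self.amh_bins)):
            if bins is not None:
                arr = np.asarray(bins, dtype=float)
                if arr.size and np.any(np.diff(arr) <= 0):
                    raise ConfigError(f"{label} cut-points must be strictly increasing")
        if self.name == "model0":
            for label, bins in (("age_bins", self.age_bins), ("amh_bins", self.amh_bins)):
                if bins is not None and len(bins) < 1:
                    raise ConfigError(f"model0 needs >=1 cut-point in {label} (>=2 bins)")

    @property
    def has_bins(self) -> bool:
        return self.age_bins is not None and self.amh_bins is not None

    def feature_names(self) -> list[str]:
        if self.name == "model1":
            return ["age", "amh"]
        if self.name == "model2":
            return ["age", "age^2", "amh", "amh^2", "amh^3"]
        if not self.has_bins:
            raise ConfigError("model0 feature names require resolved bins")
        names = [f"age_bin{i}" for i in range(1, len(self.age_bins) + 1)]
        names += [f"amh_bin{i}" for i in range(1, len(self.amh_bins) + 1)]
        return names


@dataclass(frozen=True, eq=False)
class FittedPorModel:
    """A maximum-likelihood fitted POR model.

    ``beta`` holds the intercept first, then one coefficient per design
    column in the order given by ``spec.feature_names()``.
    """

    spec: ModelSpec
    beta: np.ndarray
    n_fit: int
    log_likelihood: float
    converged: bool
    column_sd: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "spec": {
                "name": self.spec.name,
                "age_bins": list(self.spec.age_bins) if self.spec.age_bins else None,
                "amh_bins": list(self.spec.amh_bins) if self.spec.amh_bins else None,
                "center": self.spec.center,
                "center_age": self.spec.center_age,
                "center_amh": self.spec.center_amh,
            },
            "feature_names": self.spec.feature_names(),
            "beta": [float(b) for b in self.beta],
            "n_fit": int(self.n_fit),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedPorModel":
        s = d["spec"]
        spec = ModelSpec(
            name=s["name"],
            age_bins=tuple(s["age_bins"]) if s.get("age_bins") else None,
            amh_bins=tuple(s["amh_bins"]) if s.get("amh_bins") else None,
            center=bool(s.get("center", False)),
            center_age=float(s.get("center_age", DEFAULT_CENTER_AGE)),
            center_amh=float(s.get("center_amh", DEFAULT_CENTER_AMH)),
        )
        return cls(
            spec=spec,
            beta=np.asarray(d["beta"], dtype=float),
            n_fit=int(d["n_fit"]),
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedPorModel":
        return cls.from_dict(json.loads(text))


def _bin_indicators(values: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Indicator columns for ordered bins; reference (lowest) bin dropped.

    Values below the first cut fall in the reference bin; values at or above
    the last cut fall in the top bin — out-of-range values are absorbed by
    the outermost bins rather than rejected.
    """
    idx = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
    n_bins = len(cuts) + 1
    out = np.zeros((values.size, n_bins - 1))
    for j in range(1, n_bins):
        out[:, j - 1] = idx == j
    return out


def build_design_matrix(
    ages: np.ndarray, amhs: np.ndarray, spec: ModelSpec
) -> np.ndarray:
    """Design columns (no intercept) for vectors of age and AMH."""
    ages = np.asarray(ages, dtype=float)
    amhs = np.asarray(amhs, dtype=float)
    if np.any(~np.isfinite(ages)) or np.any(~np.isfinite(amhs)):
        raise InvalidRecordError("age and AMH must be finite to build the design")
    if spec.name == "model0":
        if not spec.has_bins:
            raise ConfigError(
                "model0 design requires cut-points; fit resolves them from "
                "training quintiles when unspecified"
            )
        return np.hstack(
            [_bin_indicators(ages, spec.age_bins), _bin_indicators(amhs, spec.amh_bins)]
        )
    a = ages - spec.center_age if spec.center else ages
    m = amhs - spec.center_amh if spec.center else amhs
    if spec.name == "model1":
        return np.column_stack([a, m])
    return np.column_stack([a, a**2, m, m**2, m**3])


def build_design(record: CohortRecord, spec: ModelSpec) -> np.ndarray:
    """Feature vector for one record under ``spec`` (intercept excluded)."""
    return build_design_matrix(
        np.array([record.age_years]), np.array([record.amh_ng_ml]), spec
    )[0]


def _quintile_cuts(values: np.ndarray) -> tuple[float, ...]:
    cuts = np.unique(np.quantile(values, [0.2, 0.4, 0.6, 0.8]))
    if cuts.size < 1:
        raise DegenerateDesignError("cannot derive bins from a constant predictor")
    return tuple(float(c) for c in cuts)


def resolve_model0_bins(cohort: Sequence[CohortRecord], spec: ModelSpec) -> ModelSpec:
    """Fill missing model0 cut-points with training-cohort quintiles."""
    if spec.name != "model0" or spec.has_bins:
        return spec
    ages = np.array([r.age_years for r in cohort])
    amhs = np.array([r.amh_ng_ml for r in cohort])
    return replace(
        spec,
        age_bins=spec.age_bins or _quintile_cuts(ages),
        amh_bins=spec.amh_bins or _quintile_cuts(amhs),
    )


def fit_por_model(
    cohort: Sequence[CohortRecord],
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedPorModel:
    """Fit ``spec`` by maximum likelihood on records with an outcome.

    Newton/IRLS iterations stop when the log-likelihood change falls below
    ``tol``.  Complete separation is detected when the fitted linear
    predictor classifies the sample perfectly and is flagged
    (``converged=False``) with a warning rather than raised.

    Raises
    ------
    DegenerateFitError
        If only one outcome class is present.
    DegenerateDesignError
        If a design column has zero variance (rank deficiency).
    """
    usable = outcome_subset(cohort)
    if len(usable) < MIN_FIT_N:
        warnings.warn(
            f"fitting on only {len(usable)} records (recommended >= {MIN_FIT_N}); "
            "estimates may be unstable",
            stacklevel=2,
        )
    y = np.array([float(r.por) for r in usable])
    if y.size == 0 or len(np.unique(y)) < 2:
        raise DegenerateFitError("both POR outcome classes must be present to fit")

    spec = resolve_model0_bins(usable, spec)
    ages = np.array([r.age_years for r in usable])
    amhs = np.array([r.amh_ng_ml for r in usable])
    X = build_design_matrix(ages, amhs, spec)

    sd = X.std(axis=0)
    if np.any(sd <= 1e-12):
        bad = [spec.feature_names()[j] for j in np.flatnonzero(sd <= 1e-12)]
        raise DegenerateDesignError(
            f"zero-variance design column(s) {bad}; the coefficient is not identifiable"
        )

    Xc = sm.add_constant(X, prepend=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        logit = sm.Logit(y, Xc)
        try:
            result = logit.fit(
                method="newton", maxiter=max_iter, tol=tol, disp=False,
                warn_convergence=False,
            )
        except np.linalg.LinAlgError:
            # Newton's Hessian can go singular on tiny or near-separated
            # cohorts; quasi-Newton is slower but does not invert it.
            result = logit.fit(
                method="bfgs", maxiter=10 * max_iter, gtol=tol, disp=False,
                warn_convergence=False,
            )
    beta = np.asarray(result.params, dtype=float)
    converged = bool(result.mle_retvals.get("converged", False))

    eta = Xc @ beta
    if eta[y == 1].min() - eta[y == 0].max() > SEPARATION_MARGIN:
        warnings.warn(
            "possible complete separation: the fitted linear predictor "
            "classifies the sample perfectly, so the MLE is unbounded; fit "
            "flagged as non-converged",
            stacklevel=2,
        )
        converged = False

    return FittedPorModel(
        spec=spec,
        beta=beta,
        n_fit=int(y.size),
        log_likelihood=float(result.llf),
        converged=converged,
        column_sd=sd,
    )


def linear_predictor(model: FittedPorModel, ages, amhs) -> np.ndarray:
    X = build_design_matrix(np.atleast_1d(ages), np.atleast_1d(amhs), model.spec)
    return model.beta[0] + X @ model.beta[1:]


def predict_por_probabilities(model: FittedPorModel, cohort: Sequence[CohortRecord]) -> np.ndarray:
    """Vectorized inverse-logit POR probabilities for a cohort."""
    ages = np.array([r.age_years for r in cohort])
    amhs = np.array([r.amh_ng_ml for r in cohort])
    eta = linear_predictor(model, ages, amhs)
    # expit, computed stably for large |eta|
    with np.errstate(over="ignore"):
        p = np.where(eta >= 0, 1.0 / (1.0 + np.exp(-eta)), np.exp(eta) / (1.0 + np.exp(eta)))
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def predict_por_probability(model: FittedPorModel, record: CohortRecord) -> float:
    """POR probability ``p = expit(b0 + b.x)`` for a single record."""
    return float(predict_por_probabilities(model, [record])[0])
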