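"""Discrimination, calibration and reclassification metrics.

AUC is the Mann–Whitney concordance probability: the chance that a randomly
chosen event receives a higher predicted probability than a randomly chosen
non-event, ties counting one half.  Calibration compares mean predicted
probability with the observed event proportion inside bins of predicted
risk.  The category-free net reclassification improvement (NRI) sums the
signed movement of predicted risk between a reference and a new model,
separately among events and non-events:

    NRI = [P(up | event) - P(down | event)]
        + [P(down | non-event) - P(up | non-event)]

Confidence intervals are percentile bootstrap, seeded for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UndefinedMetricError
from .records import CohortRecord

DEFAULT_BOOTSTRAP_B = 2000
DEFAULT_BOOTSTRAP_SEED = 20170101
#: Default age strata boundaries: <=30, >30-<=40, >40 years.
DEFAULT_AGE_STRATA = (30.0, 40.0)
#: The low-risk zoom window highlighted in calibration reporting.
ZOOM_RANGE = (0.0, 0.25)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-bin calibration rows plus the low-probability zoom sub-table."""

    table: pd.DataFrame          # bin_lo, bin_hi, n, mean_predicted, observed
    zoom: pd.DataFrame           # same columns restricted to predicted p in [0, 0.25]
    n: int
    binning: str                 # "quantile" or "width"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    calibration: CalibrationTable
    nri_continuous: float | None
    nri_ci: tuple[float, float] | None
    n: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "nri_continuous": self.nri_continuous,
            "nri_ci": list(self.nri_ci) if self.nri_ci is not None else None,
            "n": self.n,
            "calibration": self.calibration.table.to_dict(orient="records"),
            "calibration_zoom": self.calibration.zoom.to_dict(orient="records"),
        }


def _check_binary(labels: np.ndarray, what: str) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise UndefinedMetricError(f"{what} is undefined with a single outcome class")


def auc_point(labels, probs) -> float:
    """Mann–Whitney AUC via midranks; ties between classes count 0.5."""
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must have equal length")
    _check_binary(labels, "AUC")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(probs)  # midranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _percentile_ci(stats: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compute_auc(
    labels,
    probs,
    n_boot: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """AUC with a seeded percentile-bootstrap confidence interval.

    Bootstrap resamples drawn with only one class present are redrawn
    implicitly by resampling cases and controls separately (stratified),
    which keeps every resample's AUC defined.
    """
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    point = auc_point(labels, probs)
    if n_boot <= 0:
        return point, (point, point)
    rng = np.random.default_rng(seed)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        q = rng.choice(neg, size=neg.size, replace=True)
        merged = np.concatenate([p, q])
        lab = np.concatenate([np.ones(p.size), np.zeros(q.size)])
        stats[b] = auc_point(lab, merged)
    return point, _percentile_ci(stats, ci_level)


def nri_point(labels, probs_reference, probs_new) -> float:
    """Category-free NRI; ties in predicted risk contribute zero."""
    labels = np.asarray(labels, dtype=float)
    ref = np.asarray(probs_reference, dtype=float)
    new = np.asarray(probs_new, dtype=float)
    if not (labels.shape == ref.shape == new.shape):
        raise ValueError("labels and both probability vectors must have equal length")
    _check_binary(labels, "NRI")
    delta = np.sign(new - ref)
    events = delta[labels == 1]
    nonevents = delta[labels == 0]
    return float(events.mean() - nonevents.mean())


def continuous_nri(
    labels,
    probs_reference,
    probs_new,
    n_boot: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Continuous NRI with a seeded stratified percentile-bootstrap CI."""
    labels = np.asarray(labels, dtype=float)
    ref = np.asarray(probs_reference, dtype=float)
    new = np.asarray(probs_new, dtype=float)
    point = nri_point(labels, ref, new)
    if n_boot <= 0:
        return point, (point, point)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(idx_pos, size=idx_pos.size, replace=True)
        iq = rng.choice(idx_neg, size=idx_neg.size, replace=True)
        idx = np.concatenate([ip, iq])
        stats[b] = nri_point(labels[idx], ref[idx], new[idx])
    return point, _percentile_ci(stats, ci_level)


def categorical_nri(labels, probs_reference, probs_new, thresholds: Sequence[float]) -> float:
    """NRI over user-supplied risk categories (movement across thresholds)."""
    labels = np.asarray(labels, dtype=float)
    _check_binary(labels, "NRI")
    cuts = np.asarray(sorted(thresholds), dtype=float)
    cat_ref = np.searchsorted(cuts, np.asarray(probs_reference, dtype=float), side="right")
    cat_new = np.searchsorted(cuts, np.asarray(probs_new, dtype=float), side="right")
    delta = np.sign(cat_new - cat_ref)
    return float(delta[labels == 1].mean() - delta[labels == 0].mean())


def calibration_table(
    labels,
    probs,
    n_bins: int = 10,
    binning: str = "quantile",
) -> CalibrationTable:
    """Bin predicted probabilities and compare with observed event rates.

    Bins are equal-frequency (quantile) by default; ``binning="width"``
    gives equal-width bins on [0, 1].  If fewer distinct records than bins
    exist, the bin count is reduced with a warning.  Also returns the
    sub-table restricted to predicted probability 0–0.25, where most of the
    screened population concentrates.
    """
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = labels.size
    if n < n_bins:
        warnings.warn(
            f"only {n} records for {n_bins} bins; reducing to {max(n, 1)} bins",
            stacklevel=2,
        )
        n_bins = max(n, 1)

    if binning == "quantile":
        edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 2:  # all probabilities identical: one bin
            edges = np.array([edges[0], edges[0]])
    elif binning == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")

    idx = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)
    rows = []
    for j in range(edges.size - 1):
        mask = idx == j
        nj = int(mask.sum())
        if nj == 0:
            continue
        rows.append(
            {
                "bin_lo": float(edges[j]),
                "bin_hi": float(edges[j + 1]),
                "n": nj,
                "mean_predicted": float(probs[mask].mean()),
                "observed": float(labels[mask].mean()),
            }
        )
    table = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n", "mean_predicted", "observed"])
    zoom = table[table["mean_predicted"] <= ZOOM_RANGE[1]].reset_index(drop=True)
    return CalibrationTable(table=table, zoom=zoom, n=n, binning=binning)


def evaluate_model(
    labels,
    probs,
    probs_reference=None,
    n_bins: int = 10,
    n_boot: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> EvaluationReport:
    """Full evaluation: AUC + CI, calibration table, and NRI vs a reference."""
    auc, auc_ci = compute_auc(labels, probs, n_boot=n_boot, seed=seed)
    cal = calibration_table(labels, probs, n_bins=n_bins)
    nri = nri_ci = None
    if probs_reference is not None:
        nri, nri_ci = continuous_nri(labels, probs_reference, probs, n_boot=n_boot, seed=seed)
    return EvaluationReport(
        auc=auc,
        auc_ci=auc_ci,
        calibration=cal,
        nri_continuous=nri,
        nri_ci=nri_ci,
        n=int(np.asarray(labels).size),
    )


def plot_calibration(tables: dict[str, CalibrationTable], path, zoom: bool = True) -> None:
    """Calibration plot (mean predicted vs observed) for one or more models.

    Writes a one- or two-panel figure: the full 0-1 range and, when
    ``zoom``, the 0-0.25 window where most of the screened population lies.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if zoom else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4.5), squeeze=False)
    for ax, window in zip(axes[0], [(0, 1), ZOOM_RANGE][:n_panels]):
        ax.plot(window, window, "k--", lw=1, label="ideal")
        for name, cal in tables.items():
            df = cal.table
            ax.plot(df["mean_predicted"], df["observed"], "o-", ms=4, label=name)
        ax.set_xlim(window)
        ax.set_ylim(window)
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("observed event proportion")
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def amh_summary_by_age_strata(
    cohort: Sequence[CohortRecord],
    strata: Sequence[float] = DEFAULT_AGE_STRATA,
) -> pd.DataFrame:
    """Median and quartiles of AMH within age strata.

    Strata are closed on the right: with the default cut-points (30, 40)
    the groups are age <= 30, 30 < age <= 40 and age > 40, so a woman aged
    exactly 30 belongs to the youngest stratum.  Percentiles use linear
    interpolation between order statistics.  Empty strata appear with
    ``n = 0`` and NaN percentiles.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cuts = np.asarray(sorted(strata), dtype=float)
    ages = np.array([r.age_years for r in cohort])
    amhs = np.array([r.amh_ng_ml for r in cohort])
    # side="left": age equal to a cut-point stays in the lower stratum
    idx = np.searchsorted(cuts, ages, side="left")

    labels = []
    prev = None
    for c in cuts:
        labels.append(f"<={c:g}" if prev is None else f">{prev:g}-<={c:g}")
        prev = c
    labels.append(f">{prev:g}")

    rows = []
    for j, label in enumerate(labels):
        vals = amhs[idx == j]
        if vals.size == 0:
            rows.append({"stratum": label, "n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan})
        else:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"stratum": label, "n": int(vals.size), "median": float(med),
                 "q25": float(q25), "q75": float(q75)}
            )
    return pd.DataFrame(rows, columns=["stratum", "n", "median", "q25", "q75"])
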