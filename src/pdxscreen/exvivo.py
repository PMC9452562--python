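"""Ex vivo drug-response readouts: spheroid areas, EdU fractions, ROC cutoff,
and sigmoidal IC50 / fold-change estimation for cell-line dose-response assays.

Spheroid areas and EdU fractions are expressed as percent of the vehicle
condition; the ex vivo response call uses the ROC-derived area-change cutoff
(default -25%, boundary inclusive: a change of exactly -25 calls sensitive).
Dose-response plates are day0-normalized, vehicle-relativized, and fit with a
four-parameter logistic; the IC50 is the dose at which the fitted curve crosses
50% of control growth (never extrapolated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from . import biomarkers, stats
from .exceptions import (
    InvalidInputError,
    InsufficientDataError,
    NormalizationError,
)

__all__ = [
    "SpheroidReadout",
    "DosePlate",
    "IC50Result",
    "RocCutoffResult",
    "relative_spheroid_area",
    "edu_fraction",
    "relative_edu",
    "classify_exvivo_response",
    "roc_optimal_cutoff",
    "fit_ic50",
    "fold_change",
]

EXVIVO_CUTOFF_PCT = -25.0


@dataclass
class SpheroidReadout:
    """Replicate spheroid areas per condition for one model.

    ``areas`` maps condition label -> replicate area values; a vehicle
    condition must be present for any relative readout.
    """

    model_id: str
    areas: Mapping[str, Sequence[float]]
    readout_day: int = 7
    vehicle: str = "vehicle"

    def __post_init__(self) -> None:
        for cond, vals in self.areas.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0 or (arr <= 0).any() or not np.isfinite(arr).all():
                raise InvalidInputError(
                    f"areas for condition {cond!r} must be positive and finite"
                )


def relative_spheroid_area(
    readout: SpheroidReadout, agg: str = "mean"
) -> pd.DataFrame:
    """Percent-of-vehicle spheroid area per condition.

    relative = 100 * agg(treated) / agg(vehicle); change = relative - 100.
    ``agg`` is "mean" (default, mirroring mean-spheroid-area reporting) or
    "median".
    """
    if readout.vehicle not in readout.areas:
        raise NormalizationError(
            f"model {readout.model_id} lacks a {readout.vehicle!r} condition"
        )
    agg_fn = {"mean": np.mean, "median": np.median}.get(agg)
    if agg_fn is None:
        raise InvalidInputError(f"unknown aggregation {agg!r}")
    ref = float(agg_fn(np.asarray(readout.areas[readout.vehicle], dtype=float)))
    rows = []
    for cond, vals in readout.areas.items():
        rel = 100.0 * float(agg_fn(np.asarray(vals, dtype=float))) / ref
        rows.append(
            {
                "model_id": readout.model_id,
                "condition": cond,
                "relative_pct": rel,
                "change_pct": rel - 100.0,
            }
        )
    return pd.DataFrame(rows)


def edu_fraction(edu_positive: int, total_nuclei: int) -> float:
    """Percent EdU-positive nuclei: 100 * positive / total."""
    if total_nuclei <= 0:
        raise InvalidInputError("total_nuclei must be positive")
    if not 0 <= edu_positive <= total_nuclei:
        raise InvalidInputError(
            f"edu_positive={edu_positive} outside [0, {total_nuclei}]"
        )
    return 100.0 * edu_positive / total_nuclei


def relative_edu(
    treated_pcts: Sequence[float], vehicle_pcts: Sequence[float]
) -> float:
    """Mean EdU fraction of treated spheroids as percent of the vehicle mean."""
    t = np.asarray(treated_pcts, dtype=float)
    v = np.asarray(vehicle_pcts, dtype=float)
    if v.size == 0 or v.mean() == 0:
        raise NormalizationError("vehicle EdU fractions missing or all zero")
    return 100.0 * t.mean() / v.mean()


def classify_exvivo_response(
    area_change_pct: float, cutoff: float = EXVIVO_CUTOFF_PCT
) -> str:
    """Sensitive iff the spheroid-area change is at or below the cutoff
    (a reduction at least as deep as the cutoff)."""
    if not np.isfinite(area_change_pct):
        raise InvalidInputError("area change must be finite")
    return "sensitive" if area_change_pct <= cutoff else "resistant"


@dataclass
class RocCutoffResult:
    """Full ROC over area-change thresholds plus the Youden-optimal cutoff."""

    roc: stats.ROCResult
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


def roc_optimal_cutoff(
    changes: Sequence[float], labels: Sequence, positive="sensitive"
) -> RocCutoffResult:
    """ROC of the area change for response prediction.

    Lower (more negative) changes indicate the positive (sensitive) class, so
    the ROC scores are the negated changes and the Youden search runs in the
    low_is_positive direction.
    """
    c = np.asarray(changes, dtype=float)
    roc = stats.roc_points(-c, labels, positive=positive)
    opt = biomarkers.youden_cutoff(
        c, labels, direction="low_is_positive", positive=positive
    )
    return RocCutoffResult(
        roc=roc,
        auc=roc.auc,
        threshold=opt.threshold,
        sensitivity=opt.sensitivity,
        specificity=opt.specificity,
    )


@dataclass
class DosePlate:
    """Day-0/day-6 growth readouts on a dose grid, replicate-structured.

    ``doses`` includes 0 for the vehicle wells. ``day0``/``day6`` are
    (n_doses, n_replicates) arrays of raw growth values.
    """

    doses: np.ndarray
    day0: np.ndarray
    day6: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.day0 = np.atleast_2d(np.asarray(self.day0, dtype=float))
        self.day6 = np.atleast_2d(np.asarray(self.day6, dtype=float))
        if self.day0.shape != self.day6.shape:
            raise InvalidInputError("day0 and day6 shapes differ")
        if self.day0.shape[0] != self.doses.size:
            raise InvalidInputError("dose grid does not match plate rows")
        if (self.doses < 0).any():
            raise InvalidInputError("doses must be non-negative")
        if 0.0 not in self.doses:
            raise NormalizationError("plate lacks vehicle (dose 0) wells")
        if np.count_nonzero(self.doses) < 4:
            raise InsufficientDataError("need >= 4 distinct non-zero doses")

    def normalized_response(self) -> pd.DataFrame:
        """Percent-of-vehicle growth per non-zero dose.

        Per well, growth = day6/day0 (day-0 normalization first); the
        per-dose mean growth is then relativized to the vehicle mean growth.
        """
        growth = self.day6 / self.day0
        vehicle = growth[self.doses == 0].mean()
        mask = self.doses > 0
        resp = 100.0 * growth[mask].mean(axis=1) / vehicle
        return pd.DataFrame({"dose": self.doses[mask], "response_pct": resp})


@dataclass
class IC50Result:
    """4PL fit: IC50 (dose at 50% of control growth) and curve parameters."""

    ic50: float | None
    params: dict = field(default_factory=dict)
    not_reached: bool = False


def _four_pl(logd, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))


def fit_ic50(plate: DosePlate) -> IC50Result:
    """Fit a four-parameter logistic on log10 dose and report the dose at 50%
    of control growth.

    Initialization comes from the response quartiles; the hill-slope sign is
    left free; the loss is least squares on the percent scale. If the fitted
    curve never crosses the 50% level within the observed dose range the
    result carries ``not_reached=True`` and no extrapolated IC50.
    """
    norm = plate.normalized_response()
    logd = np.log10(norm["dose"].to_numpy())
    resp = norm["response_pct"].to_numpy()
    p0 = [
        float(np.quantile(resp, 0.05)),
        float(np.quantile(resp, 0.95)),
        float(np.median(logd)),
        1.0,
    ]
    try:
        with warnings.catch_warnings():
            # a perfect (noise-free) fit has singular covariance; only the
            # point estimate is used here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_four_pl, logd, resp, p0=p0, maxfev=20000)
    except RuntimeError:
        return IC50Result(ic50=None, params={}, not_reached=True)
    bottom, top, log_ic50, hill = popt
    params = {
        "bottom": float(bottom),
        "top": float(top),
        "log10_inflection": float(log_ic50),
        "hill": float(hill),
    }
    # Solve 4PL(x) = 50 analytically on the log scale.
    lo, hi = min(bottom, top), max(bottom, top)
    if not lo < 50.0 < hi or hill == 0:
        return IC50Result(ic50=None, params=params, not_reached=True)
    ratio = (top - 50.0) / (50.0 - bottom)
    x50 = log_ic50 + np.log10(ratio) / hill
    if not logd.min() - 1e-9 <= x50 <= logd.max() + 1e-9:
        return IC50Result(ic50=None, params=params, not_reached=True)
    return IC50Result(ic50=float(10.0**x50), params=params, not_reached=False)


def fold_change(ic50_test: float, ic50_reference: float) -> float:
    """IC50 fold change relative to a reference condition."""
    if ic50_test <= 0 or ic50_reference <= 0:
        raise InvalidInputError("IC50 values must be positive")
    return ic50_test / ic50_reference
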