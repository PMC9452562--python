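"""Tumor growth: caliper volumes, percent change, mRECIST calls, cohort rates.

The unit of response calling is a :class:`GrowthSeries` — the ordered caliper
record of one tumor (model, animal, arm). Volumes come from the ellipsoid
formula V = (length x width^2) * pi/6; responses are banded RECIST-like on the
best (most negative) percent volume change:

    CR <= -95 < PR <= -30 < SD <= +20 < PD

Cohorts are summarized as the preclinical response rate pRR = (CR+PR)/n and
preclinical benefit rate pCB = (CR+PR+SD)/n, with bootstrap standard errors on
mean percent change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyCohortError,
    InsufficientDataError,
    InvalidInputError,
    InvalidMeasurementError,
    NotEvaluableError,
)

__all__ = [
    "MRECIST_CLASSES",
    "CaliperMeasurement",
    "GrowthSeries",
    "ResponseCall",
    "CohortSummary",
    "ellipsoid_volume",
    "classify_mrecist",
    "rtv_band",
    "pct_volume_change",
    "best_response",
    "relative_tumor_volume",
    "response_call",
    "call_model_responses",
    "cohort_summary",
    "bootstrap_se",
    "series_from_table",
    "round_half_away",
]

MRECIST_CLASSES = ("CR", "PR", "SD", "PD")

#: default tolerance (days) when the requested day has no measurement
NEAREST_DAY_WINDOW = 3

#: earliest day eligible for the best-response minimum. Without a floor the
#: first post-baseline measurement (near 0% change by continuity) would sit in
#: the SD band for every tumor; preclinical mRECIST takes the best response
#: over measurements at >= 10 days on treatment.
MIN_BEST_RESPONSE_DAY = 10


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (report parity)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def ellipsoid_volume(length: float, width: float) -> float:
    """Ellipsoid tumor volume in mm^3 from two caliper dimensions in mm.

    V = (L x W^2) * pi/6 with the smaller of the two dimensions squared, so the
    call is symmetric in its arguments.
    """
    if not (np.isfinite(length) and np.isfinite(width)):
        raise InvalidMeasurementError("caliper dimensions must be finite")
    if length <= 0 or width <= 0:
        raise InvalidMeasurementError(
            f"caliper dimensions must be positive, got ({length}, {width})"
        )
    long_d, short_d = max(length, width), min(length, width)
    return (long_d * short_d**2) * math.pi / 6.0


@dataclass(frozen=True)
class CaliperMeasurement:
    """One caliper record. Width/length are swapped on ingest if needed."""

    model_id: str
    animal_id: str
    arm: str
    day: int
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InvalidMeasurementError(f"day must be >= 0, got {self.day}")
        if not (np.isfinite(self.length_mm) and np.isfinite(self.width_mm)):
            raise InvalidMeasurementError("caliper dimensions must be finite")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise InvalidMeasurementError("caliper dimensions must be positive")
        if self.width_mm > self.length_mm:
            long_d, short_d = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", long_d)
            object.__setattr__(self, "width_mm", short_d)

    @property
    def volume(self) -> float:
        return ellipsoid_volume(self.length_mm, self.width_mm)


@dataclass
class GrowthSeries:
    """Ordered caliper measurements for one tumor."""

    model_id: str
    animal_id: str
    arm: str
    measurements: list[CaliperMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.measurements = sorted(self.measurements, key=lambda m: m.day)
        days = [m.day for m in self.measurements]
        if len(set(days)) != len(days):
            raise InvalidMeasurementError(
                f"duplicate measurement days for {self.model_id}/{self.animal_id}"
            )

    @property
    def days(self) -> list[int]:
        return [m.day for m in self.measurements]

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.volume for m in self.measurements])

    def baseline_volume(self) -> float:
        if not self.measurements or self.measurements[0].day != 0:
            raise NotEvaluableError(
                f"series {self.model_id}/{self.animal_id} lacks a day-0 baseline"
            )
        return self.measurements[0].volume

    def volume_at(self, day: int, window: int = NEAREST_DAY_WINDOW) -> float:
        """Volume at ``day``; falls back to the nearest record within ±window
        days (earlier record wins a tie)."""
        days = np.array(self.days)
        dist = np.abs(days - day)
        i = int(np.argmin(dist))  # argmin takes the earlier day on ties
        if dist[i] > window:
            raise NotEvaluableError(
                f"no measurement within ±{window} d of day {day} for "
                f"{self.model_id}/{self.animal_id}"
            )
        return self.measurements[i].volume


def classify_mrecist(best_pct_change: float) -> str:
    """Band a best percent volume change into CR/PR/SD/PD.

    Boundaries are closed on the sensitive side: -95 is CR, -30 is PR,
    +20 is SD; anything above +20 is PD.
    """
    x = float(best_pct_change)
    if not np.isfinite(x):
        raise InvalidInputError(f"percent change must be finite, got {x}")
    if x <= -95:
        return "CR"
    if x <= -30:
        return "PR"
    if x <= 20:
        return "SD"
    return "PD"


def rtv_band(rtv: float) -> str:
    """Relative-tumor-volume band: PD > 1.2, SD in [0.7, 1.2], PR/CR < 0.7."""
    if not np.isfinite(rtv) or rtv < 0:
        raise InvalidInputError(f"RTV must be finite and non-negative, got {rtv}")
    if rtv > 1.2:
        return "PD"
    if rtv >= 0.7:
        return "SD"
    return "PR/CR"


def pct_volume_change(
    series: GrowthSeries, day: int, window: int = NEAREST_DAY_WINDOW
) -> float:
    """Percent tumor-volume change at ``day`` vs the day-0 baseline:
    100 * (V_day - V_0) / V_0."""
    v0 = series.baseline_volume()
    vd = series.volume_at(day, window=window)
    return 100.0 * (vd - v0) / v0


def best_response(
    series: GrowthSeries, min_day: int = MIN_BEST_RESPONSE_DAY
) -> float:
    """Best (minimum) percent volume change over days >= ``min_day``."""
    v0 = series.baseline_volume()
    post = [m for m in series.measurements if m.day >= min_day]
    if not post:
        raise NotEvaluableError(
            f"series {series.model_id}/{series.animal_id} has no record at "
            f"day >= {min_day}"
        )
    return min(100.0 * (m.volume - v0) / v0 for m in post)


def relative_tumor_volume(series: GrowthSeries) -> pd.DataFrame:
    """RTV_t = V_t / V_0 per day, with the PD/SD/PR-CR band label."""
    v0 = series.baseline_volume()
    rows = [
        {"day": m.day, "rtv": m.volume / v0, "band": rtv_band(m.volume / v0)}
        for m in series.measurements
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResponseCall:
    """Per-tumor (or per-model) response: the mRECIST class is determined
    solely by the best percent change."""

    model_id: str
    arm: str
    best_pct_change: float
    day_pct_change: float | None  # change at the reporting day (e.g. 35)
    mrecist: str
    evaluable: bool = True


def response_call(
    series: GrowthSeries,
    day: int = 35,
    window: int = NEAREST_DAY_WINDOW,
    min_day: int = MIN_BEST_RESPONSE_DAY,
) -> ResponseCall:
    """Call one series: best response over the window drives the class; the
    day-``day`` change is reported separately (None if follow-up is short)."""
    best = best_response(series, min_day=min_day)
    try:
        at_day = pct_volume_change(series, day, window=window)
    except NotEvaluableError:
        at_day = None
    return ResponseCall(
        model_id=series.model_id,
        arm=series.arm,
        best_pct_change=best,
        day_pct_change=at_day,
        mrecist=classify_mrecist(best),
    )


def series_from_table(df: pd.DataFrame) -> list[GrowthSeries]:
    """Split a measurement table (model_id, animal_id, arm, day, length_mm,
    width_mm) into one GrowthSeries per tumor."""
    out = []
    for (model, animal, arm), grp in df.groupby(
        ["model_id", "animal_id", "arm"], sort=True
    ):
        ms = [
            CaliperMeasurement(
                model_id=str(model),
                animal_id=str(animal),
                arm=str(arm),
                day=int(r.day),
                length_mm=float(r.length_mm),
                width_mm=float(r.width_mm),
            )
            for r in grp.itertuples()
        ]
        out.append(GrowthSeries(str(model), str(animal), str(arm), ms))
    return out


def call_model_responses(
    df: pd.DataFrame,
    day: int = 35,
    arm: str | None = None,
    window: int = NEAREST_DAY_WINDOW,
    min_day: int = MIN_BEST_RESPONSE_DAY,
) -> pd.DataFrame:
    """Model-level response calls from a measurement table.

    Per-tumor percent-change trajectories are averaged across animals of a
    model/arm at each shared day (mirroring mean-of-tumors waterfall
    reporting) and the model is classified on the best mean change at days
    >= ``min_day``.
    """
    if arm is not None:
        df = df[df["arm"] == arm]
    rows = []
    for (model, arm_label), grp in df.groupby(["model_id", "arm"], sort=True):
        series = series_from_table(grp)
        per_day: dict[int, list[float]] = {}
        for s in series:
            v0 = s.baseline_volume()
            for m in s.measurements:
                if m.day > 0:
                    per_day.setdefault(m.day, []).append(
                        100.0 * (m.volume - v0) / v0
                    )
        if not per_day:
            continue
        mean_by_day = {d: float(np.mean(v)) for d, v in per_day.items()}
        eligible = [v for d, v in mean_by_day.items() if d >= min_day]
        if not eligible:
            continue
        best = min(eligible)
        # reporting-day mean change, nearest within the window
        days = np.array(sorted(mean_by_day))
        dist = np.abs(days - day)
        at_day = (
            mean_by_day[int(days[int(np.argmin(dist))])]
            if dist.min() <= window
            else None
        )
        rows.append(
            {
                "model_id": model,
                "arm": arm_label,
                "n_tumors": len(series),
                "best_pct_change": best,
                "day_pct_change": at_day,
                "mrecist": classify_mrecist(best),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    """Cohort-level mRECIST counts and pRR/pCB percentages.

    pRR = 100*(CR+PR)/n, pCB = 100*(CR+PR+SD)/n; the rounded values use
    half-away-from-zero rounding for report parity.
    """

    counts: dict[str, int]
    n_evaluable: int
    prr_pct: float
    pcb_pct: float
    prr_pct_rounded: int
    pcb_pct_rounded: int


def cohort_summary(calls: Iterable) -> CohortSummary:
    """Summarize response calls (ResponseCall objects, class strings, or a
    mapping of class -> count) into counts and pRR/pCB."""
    if isinstance(calls, dict):
        counts = {c: int(calls.get(c, 0)) for c in MRECIST_CLASSES}
    else:
        counts = {c: 0 for c in MRECIST_CLASSES}
        for call in calls:
            cls = call.mrecist if isinstance(call, ResponseCall) else str(call)
            if cls not in counts:
                raise InvalidInputError(f"unknown mRECIST class {cls!r}")
            counts[cls] += 1
    n = sum(counts.values())
    if n == 0:
        raise EmptyCohortError("no evaluable response calls")
    prr = 100.0 * (counts["CR"] + counts["PR"]) / n
    pcb = 100.0 * (counts["CR"] + counts["PR"] + counts["SD"]) / n
    return CohortSummary(
        counts=counts,
        n_evaluable=n,
        prr_pct=prr,
        pcb_pct=pcb,
        prr_pct_rounded=round_half_away(prr),
        pcb_pct_rounded=round_half_away(pcb),
    )


def bootstrap_se(
    values: Sequence[float], n_boot: int = 2000, seed: int = 0
) -> float:
    """Bootstrap standard error of the mean: SD of ``n_boot`` resampled means.

    Deterministic given ``seed``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("bootstrap_se needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    return float(means.std(ddof=1))
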