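"""IHC biomarker panels and the composite CDK4/6i-resistance classifier.

p16 and total pRb are scored semiquantitatively (0-4); cyclin E1 and cyclin D1
use the Allred 0-8 scale (proportion bin 0-5 plus intensity 0-3). The composite
rule predicts resistance when any of the following fires, evaluated in order:

    basal-like intrinsic subtype  ->  resistant
    p16 >= 2                      ->  resistant
    pRb <= 2                      ->  resistant
    cyclin E1 > 4 or cyclin D1 > 6 -> resistant
    otherwise                     ->  sensitive

Cutoffs default to the Youden-optimal values above and are overridable via
:class:`CutoffSet`. The module also houses the Youden-index cutoff search,
2x2 concordance metrics, the KI67 Luminal A/B split and the ln KI67 < 1
antiproliferative-response rule, and per-SD odds ratios for continuous
H-score biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .exceptions import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidInputError,
    UnclassifiableError,
)

__all__ = [
    "SUBTYPES",
    "DEFAULT_CUTOFFS",
    "BiomarkerPanel",
    "CutoffSet",
    "PredictionCall",
    "ConcordanceReport",
    "YoudenResult",
    "OddsRatioPerSD",
    "allred_score",
    "classify_composite",
    "classify_panel_table",
    "youden_cutoff",
    "concordance",
    "ki67_luminal_split",
    "ki67_response",
    "or_per_sd",
]

SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal", "unknown")


@dataclass(frozen=True)
class CutoffSet:
    """Composite-rule cutoffs (defaults are the Youden-optimal values)."""

    p16_high_ge: int = 2
    prb_low_le: int = 2
    e1_high_gt: int = 4
    d1_high_gt: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.p16_high_ge <= 4 and 0 <= self.prb_low_le <= 4):
            raise InvalidInputError("p16/pRb cutoffs must lie in 0-4")
        if not (0 <= self.e1_high_gt <= 8 and 0 <= self.d1_high_gt <= 8):
            raise InvalidInputError("Allred cutoffs must lie in 0-8")


DEFAULT_CUTOFFS = CutoffSet()


def _check_ordinal(value, lo, hi, name) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    v = float(value)
    if not lo <= v <= hi:
        raise InvalidInputError(f"{name}={value} outside [{lo}, {hi}]")
    return v


@dataclass(frozen=True)
class BiomarkerPanel:
    """One sample's IHC scores plus intrinsic subtype. Missing scores are None."""

    sample_id: str
    p16: float | None = None
    prb: float | None = None
    cyclin_e1: float | None = None
    cyclin_d1: float | None = None
    intrinsic_subtype: str = "unknown"
    ki67_pct: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p16", _check_ordinal(self.p16, 0, 4, "p16"))
        object.__setattr__(self, "prb", _check_ordinal(self.prb, 0, 4, "prb"))
        object.__setattr__(
            self, "cyclin_e1", _check_ordinal(self.cyclin_e1, 0, 8, "cyclin_e1")
        )
        object.__setattr__(
            self, "cyclin_d1", _check_ordinal(self.cyclin_d1, 0, 8, "cyclin_d1")
        )
        if self.intrinsic_subtype not in SUBTYPES:
            raise InvalidInputError(
                f"unknown intrinsic subtype {self.intrinsic_subtype!r}"
            )


@dataclass(frozen=True)
class PredictionCall:
    """Composite-rule outcome; fired_rule is the first satisfied rule, or
    'none' exactly when the prediction is sensitive."""

    sample_id: str
    predicted: str  # "resistant" | "sensitive"
    fired_rule: str  # basal_subtype | p16_high | prb_low | cyclin_high | none


# Allred proportion bins: 0%, <1%, 1-10%, 11-33%, 34-66%, >66% -> 0..5
_ALLRED_EDGES = (0.0, 1.0, 10.0, 33.0, 66.0)


def allred_score(positive_pct: float, intensity: int) -> int:
    """Allred 0-8 score: proportion bin (0-5) plus staining intensity (0-3)."""
    if not 0 <= positive_pct <= 100:
        raise InvalidInputError(f"positive_pct={positive_pct} outside [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise InvalidInputError(f"intensity={intensity} outside 0-3")
    if positive_pct == 0:
        prop = 0
    elif positive_pct < 1:
        prop = 1
    elif positive_pct <= 10:
        prop = 2
    elif positive_pct <= 33:
        prop = 3
    elif positive_pct <= 66:
        prop = 4
    else:
        prop = 5
    return prop + int(intensity)


def classify_composite(
    panel: BiomarkerPanel, cutoffs: CutoffSet = DEFAULT_CUTOFFS
) -> PredictionCall:
    """Apply the composite resistance rule to one panel.

    A missing score cannot fire its rule; the panel is unclassifiable only if
    the subtype is unknown and all four scores are missing.
    """
    scores = (panel.p16, panel.prb, panel.cyclin_e1, panel.cyclin_d1)
    if panel.intrinsic_subtype == "unknown" and all(s is None for s in scores):
        raise UnclassifiableError(f"panel {panel.sample_id} has no rule inputs")
    if panel.intrinsic_subtype == "Basal":
        return PredictionCall(panel.sample_id, "resistant", "basal_subtype")
    if panel.p16 is not None and panel.p16 >= cutoffs.p16_high_ge:
        return PredictionCall(panel.sample_id, "resistant", "p16_high")
    if panel.prb is not None and panel.prb <= cutoffs.prb_low_le:
        return PredictionCall(panel.sample_id, "resistant", "prb_low")
    e1_high = panel.cyclin_e1 is not None and panel.cyclin_e1 > cutoffs.e1_high_gt
    d1_high = panel.cyclin_d1 is not None and panel.cyclin_d1 > cutoffs.d1_high_gt
    if e1_high or d1_high:
        return PredictionCall(panel.sample_id, "resistant", "cyclin_high")
    return PredictionCall(panel.sample_id, "sensitive", "none")


def classify_panel_table(
    df: pd.DataFrame, cutoffs: CutoffSet = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Vector form of :func:`classify_composite` over a panel table with
    columns sample_id, p16, prb, cyclin_e1, cyclin_d1, subtype[, ki67_pct]."""
    calls = []
    for r in df.itertuples():
        panel = BiomarkerPanel(
            sample_id=str(r.sample_id),
            p16=getattr(r, "p16", None),
            prb=getattr(r, "prb", None),
            cyclin_e1=getattr(r, "cyclin_e1", None),
            cyclin_d1=getattr(r, "cyclin_d1", None),
            intrinsic_subtype=getattr(r, "subtype", "unknown"),
        )
        call = classify_composite(panel, cutoffs)
        calls.append(
            {
                "sample_id": call.sample_id,
                "predicted": call.predicted,
                "fired_rule": call.fired_rule,
            }
        )
    return pd.DataFrame(calls)


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    j: float
    sensitivity: float
    specificity: float


def youden_cutoff(
    scores: Sequence[float],
    labels: Sequence,
    direction: str = "high_is_positive",
    positive="resistant",
) -> YoudenResult:
    """Threshold maximizing the Youden index J = sensitivity + specificity - 1.

    All distinct score values are candidate thresholds; a score equal to the
    threshold is called positive. Ties on J are broken toward higher
    sensitivity, then the lower threshold (favoring detection of the positive
    class).
    """
    if direction not in ("high_is_positive", "low_is_positive"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    y = stats.as_binary(labels, positive)
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes required for a cutoff search")
    s = np.asarray(scores, dtype=float)
    n_pos = y.sum()
    n_neg = y.size - n_pos
    best: YoudenResult | None = None
    for t in np.unique(s):
        pred = s >= t if direction == "high_is_positive" else s <= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        cand = YoudenResult(float(t), j, sens, spec)
        if (
            best is None
            or cand.j > best.j + 1e-12
            or (
                abs(cand.j - best.j) <= 1e-12
                and (
                    cand.sensitivity > best.sensitivity + 1e-12
                    or (
                        abs(cand.sensitivity - best.sensitivity) <= 1e-12
                        and cand.threshold < best.threshold
                    )
                )
            )
        ):
            best = cand
    assert best is not None
    return best


@dataclass(frozen=True)
class ConcordanceReport:
    """2x2 agreement between predicted and observed calls ('resistant' is the
    positive class) and the derived proportions."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def concordance(
    predicted: Sequence, observed: Sequence, positive="resistant"
) -> ConcordanceReport:
    """Concordance metrics from predicted vs observed binary calls."""
    pred = np.asarray(predicted)
    obs = np.asarray(observed)
    if pred.shape != obs.shape:
        raise InvalidInputError("predicted and observed lengths differ")
    p = stats.as_binary(pred, positive)
    o = stats.as_binary(obs, positive)
    tp = int(((p == 1) & (o == 1)).sum())
    fp = int(((p == 1) & (o == 0)).sum())
    fn = int(((p == 0) & (o == 1)).sum())
    tn = int(((p == 0) & (o == 0)).sum())
    n = tp + fp + fn + tn

    def _safe(num, den):
        return float(num) / den if den else float("nan")

    return ConcordanceReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_safe(tp, tp + fn),
        specificity=_safe(tn, tn + fp),
        accuracy=_safe(tp + tn, n),
        ppv=_safe(tp, tp + fp),
        npv=_safe(tn, tn + fn),
    )


def ki67_luminal_split(ki67_pct: float) -> str:
    """Luminal A if %KI67 < 15, Luminal B if >= 15."""
    if not 0 <= ki67_pct <= 100:
        raise InvalidInputError(f"ki67_pct={ki67_pct} outside [0, 100]")
    return "LumA" if ki67_pct < 15 else "LumB"


def ki67_response(ki67_pct_day15: float) -> str:
    """Antiproliferative response at day 15: sensitive iff ln(%KI67) < 1.

    The log is taken on the percentage as printed (sensitive iff KI67 < e%).
    Non-positive inputs are clamped to the smallest positive percentage of a
    countable cell population and therefore call sensitive.
    """
    if not np.isfinite(ki67_pct_day15):
        raise InvalidInputError("ki67_pct_day15 must be finite")
    if ki67_pct_day15 > 100:
        raise InvalidInputError("ki67_pct_day15 must be a percentage <= 100")
    value = max(float(ki67_pct_day15), 1e-6)
    return "sensitive" if np.log(value) < 1.0 else "resistant"


@dataclass(frozen=True)
class OddsRatioPerSD:
    """Univariate logistic odds ratio per 1-SD change of a continuous marker."""

    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    separation: bool
    n: int


def or_per_sd(
    biomarker_values: Sequence[float],
    responses: Sequence,
    positive="resistant",
) -> OddsRatioPerSD:
    """Odds ratio (with Wald CI and p) per standard-deviation change of a
    continuous H-score biomarker, from a univariate logistic fit on the
    z-scored marker. Separation is reported, never silently clipped."""
    x = np.asarray(biomarker_values, dtype=float)
    y = stats.as_binary(responses, positive)
    if x.size < 10:
        raise InsufficientDataError("or_per_sd needs at least 10 observations")
    if y.all() or not y.any():
        raise DegenerateLabelsError("both response classes required")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("biomarker has zero variance")
    z = (x - x.mean()) / sd
    fit = stats.logistic_fit(pd.DataFrame({"z": z}), y)
    if fit.separation or not fit.converged:
        return OddsRatioPerSD(None, None, None, None, True, int(x.size))
    return OddsRatioPerSD(
        odds_ratio=float(np.exp(fit.params["z"])),
        ci_low=float(np.exp(fit.conf_int.loc["z", "low"])),
        ci_high=float(np.exp(fit.conf_int.loc["z", "high"])),
        p=float(fit.pvalues["z"]),
        separation=False,
        n=int(x.size),
    )
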