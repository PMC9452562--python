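"""Shared statistical machinery.

Logistic regression with Wald inference (hand-rolled IRLS so that separation is
detected explicitly rather than silently clipped), Fisher's exact test,
Benjamini-Hochberg FDR adjustment, and ROC primitives. These are consumed by
the biomarker, ex vivo and genomics modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DegenerateLabelsError, DegenerateOutcomeError, InsufficientDataError

__all__ = [
    "LogisticFit",
    "ROCResult",
    "logistic_fit",
    "fisher_exact",
    "bh_adjust",
    "roc_points",
    "as_binary",
]

#: coefficient sup-norm beyond which an IRLS path is declared separated.
#: On standardized or binary designs a finite MLE essentially never exceeds
#: this magnitude (odds ratios beyond e^30 are not estimable from data).
_SEPARATION_NORM = 30.0


def as_binary(labels: Sequence, positive) -> np.ndarray:
    """Coerce an arbitrary two-level label vector to 0/1 with ``positive`` -> 1."""
    arr = np.asarray(labels)
    out = (arr == positive).astype(float)
    if positive not in set(np.unique(arr)) and not out.any():
        raise DegenerateLabelsError(f"positive label {positive!r} absent from labels")
    return out


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``params`` etc. are None when separation was detected: the MLE does not
    exist and no estimate is reported rather than a numerically diverged one.
    """

    terms: list[str]
    params: pd.Series | None
    bse: pd.Series | None
    zvalues: pd.Series | None
    pvalues: pd.Series | None
    conf_int: pd.DataFrame | None
    converged: bool
    separation: bool
    n: int
    n_iter: int = 0

    def odds_ratios(self) -> pd.DataFrame | None:
        """Exponentiated coefficients with 95% Wald intervals."""
        if self.params is None:
            return None
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(self.conf_int["low"]),
                "ci_high": np.exp(self.conf_int["high"]),
                "p": self.pvalues,
            }
        )


def _design_matrix(design, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and X.size > X.shape[1]:
            X = X.T
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


def logistic_fit(
    design,
    outcome: Sequence,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit a logistic model by iteratively reweighted least squares.

    Parameters
    ----------
    design
        Predictor table (DataFrame with named columns, or array-like). An
        intercept column is prepended unless ``add_intercept`` is False.
    outcome
        Binary outcome (0/1 or boolean).

    Returns
    -------
    LogisticFit with Wald SEs, z, two-sided p and 95% CIs per term. If the
    coefficient norm diverges (complete or quasi-complete separation) the fit
    is flagged and estimates are withheld.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _design_matrix(design, add_intercept)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("design and outcome lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateOutcomeError("outcome takes a single value")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if n <= k:
        raise InsufficientDataError(f"n={n} does not exceed number of terms ({k})")

    beta = np.zeros(k)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = p * (1.0 - p)
        # Fisher scoring step; ridge epsilon guards the near-separated boundary
        XtW = X.T * w
        H = XtW @ X + 1e-12 * np.eye(k)
        score = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > _SEPARATION_NORM:
            separation = True
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    if separation or not converged:
        return LogisticFit(
            terms=names,
            params=None,
            bse=None,
            zvalues=None,
            pvalues=None,
            conf_int=None,
            converged=False,
            separation=separation,
            n=n,
            n_iter=it,
        )

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    ci = pd.DataFrame(
        {"low": beta - 1.96 * se, "high": beta + 1.96 * se}, index=names
    )
    return LogisticFit(
        terms=names,
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        conf_int=ci,
        converged=True,
        separation=False,
        n=n,
        n_iter=it,
    )


def fisher_exact(table, continuity: bool = False) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``. The p-value is the conditional hypergeometric
    two-sided probability (sum over tables at least as extreme as observed).
    The odds ratio is the sample cross-product ratio ad/bc; with
    ``continuity=True`` 0.5 is added to every cell (Haldane-Anscombe) so zero
    cells yield a finite estimate.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if continuity or 0.0 in (a, b, c, d):
        if continuity:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            oddsratio = (a * d) / (b * c)
        else:
            oddsratio = np.inf if (a * d) > 0 else (0.0 if (b * c) > 0 else np.nan)
    else:
        oddsratio = (a * d) / (b * c)
    return float(oddsratio), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of ( m * p_(j) / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class ROCResult:
    """ROC curve over achievable thresholds plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    points: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.points = pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_points(scores: Sequence[float], labels: Sequence, positive=1) -> ROCResult:
    """ROC points (FPR, TPR) at every distinct score threshold, with AUC.

    Higher scores are taken to indicate the positive class; negate the scores
    for the opposite direction.
    """
    y = as_binary(labels, positive)
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes must be present for a ROC curve")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))
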