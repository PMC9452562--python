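"""qPCR reference-gene selection (geNorm), comparative-Ct normalization, and
group comparisons with Benjamini-Hochberg FDR.

A Ct matrix is a genes x samples DataFrame of threshold-cycle values.
Amplification efficiency is fixed at 2 (comparative Ct without efficiency
correction), so a one-cycle drop doubles the relative quantity. geNorm ranks
candidate reference genes by the stability measure M — the mean standard
deviation of a gene's pairwise log2 expression ratios with every other
candidate across samples — and iteratively excludes the least stable gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "genorm_stability",
    "genorm_select",
    "genorm_pairwise_variation",
    "normalize_ct",
    "NormalizedExpression",
    "compare_groups",
]


def _check_ct(ct: pd.DataFrame, genes: Sequence[str]) -> None:
    missing = [g for g in genes if g not in ct.index]
    if missing:
        raise InvalidInputError(f"genes absent from Ct matrix: {missing}")


def genorm_stability(ct: pd.DataFrame, candidates: Sequence[str]) -> pd.Series:
    """geNorm stability value M per candidate reference gene, ranked ascending
    (lower M = more stable).

    For genes j, k the pairwise measure A_jk is the per-sample log2 expression
    ratio, which under fixed efficiency 2 equals Ct_k - Ct_j; M_j is the mean
    over k != j of std(A_jk). Constant-ratio genes get M = 0.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise InsufficientDataError("geNorm needs >= 2 candidate genes")
    _check_ct(ct, candidates)
    sub = ct.loc[candidates].astype(float)
    if sub.shape[1] < 2:
        raise InsufficientDataError("geNorm needs >= 2 samples")
    m = {}
    for j in candidates:
        sds = [
            float((sub.loc[k] - sub.loc[j]).std(ddof=1))
            for k in candidates
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M").sort_values(kind="stable")


def genorm_select(
    ct: pd.DataFrame, candidates: Sequence[str], n_keep: int = 2
) -> tuple[list[str], list[str]]:
    """Iterative geNorm gene selection.

    Repeatedly drops the gene with the highest M until ``n_keep`` remain.
    Returns (kept genes ranked most-stable-first, exclusion order worst-first).
    """
    remaining = list(candidates)
    if n_keep < 2:
        raise InvalidInputError("geNorm cannot rank below a final pair")
    excluded: list[str] = []
    while len(remaining) > n_keep:
        m = genorm_stability(ct, remaining)
        worst = m.index[-1]
        excluded.append(str(worst))
        remaining.remove(worst)
    final = genorm_stability(ct, remaining)
    return [str(g) for g in final.index], excluded


def genorm_pairwise_variation(
    ct: pd.DataFrame, ranked_genes: Sequence[str]
) -> pd.Series:
    """Pairwise variation V_{n,n+1} between normalization factors built from
    the n and n+1 most stable genes.

    V is the std across samples of log2(NF_n / NF_{n+1}); in the original
    procedure V < 0.15 means adding the next gene is unnecessary.
    """
    genes = list(ranked_genes)
    if len(genes) < 3:
        raise InsufficientDataError("pairwise variation needs >= 3 ranked genes")
    _check_ct(ct, genes)
    q = 2.0 ** (-ct.loc[genes].astype(float))  # relative quantities
    out = {}
    for n in range(2, len(genes)):
        nf_n = np.exp(np.log(q.iloc[:n]).mean(axis=0))
        nf_n1 = np.exp(np.log(q.iloc[: n + 1]).mean(axis=0))
        out[f"V{n}/{n + 1}"] = float(np.log2(nf_n / nf_n1).std(ddof=1))
    return pd.Series(out, name="V")


@dataclass
class NormalizedExpression:
    """Comparative-Ct relative expression plus the samples excluded for
    missing reference values."""

    expression: pd.DataFrame
    excluded_samples: list[str]


def normalize_ct(
    ct: pd.DataFrame, housekeeping: Sequence[str]
) -> NormalizedExpression:
    """Geometric-mean comparative-Ct normalization.

    The per-sample normalization factor is the geometric mean of the reference
    genes' relative quantities 2^(-Ct); each target's relative expression is
    2^(-Ct_target) / NF, i.e. 2^-(Ct_target - mean(Ct_ref)). Samples with any
    missing reference Ct are excluded and reported.
    """
    hk = list(housekeeping)
    if not hk:
        raise InvalidInputError("at least one reference gene is required")
    _check_ct(ct, hk)
    ct = ct.astype(float)
    hk_ct = ct.loc[hk]
    good = hk_ct.notna().all(axis=0)
    excluded = [str(s) for s in ct.columns[~good]]
    kept = ct.loc[:, good]
    ref_mean_ct = kept.loc[hk].mean(axis=0)
    targets = [g for g in kept.index if g not in hk]
    expr = 2.0 ** (-(kept.loc[targets].sub(ref_mean_ct, axis=1)))
    return NormalizedExpression(expression=expr, excluded_samples=excluded)


def compare_groups(
    expression: pd.DataFrame,
    groups: pd.Series | dict,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-gene two-group comparison with BH-adjusted q-values.

    ``expression`` is genes x samples; ``groups`` maps sample -> group label
    (exactly two groups, >= 2 samples each). ``test`` is "ranksum"
    (Mann-Whitney U, the default when normality is not asserted) or "ttest"
    (Welch). Returns a DataFrame with statistic, p and BH q per gene.
    """
    g = pd.Series(groups)
    g = g.loc[[s for s in expression.columns if s in g.index]]
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise InvalidInputError(f"exactly two groups required, got {levels}")
    a_cols = g.index[g == levels[0]]
    b_cols = g.index[g == levels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    rows = []
    for gene in expression.index:
        a = expression.loc[gene, a_cols].astype(float).dropna()
        b = expression.loc[gene, b_cols].astype(float).dropna()
        if test == "ranksum":
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        elif test == "ttest":
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        else:
            raise InvalidInputError(f"unknown test {test!r}")
        rows.append({"gene": gene, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
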