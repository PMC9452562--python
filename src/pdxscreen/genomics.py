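"""Variant-consequence and copy-number classification, double-hit calling, and
exposure-association logistic models.

A gene is "double hit" in a sample when it carries both a coding mutation and a
heterozygous deletion — the biallelic-inactivation signature whose enrichment
among drug-exposed patients the association models test. Copy-number state is
callable from either of two dialects: segment log-ratio bands
(deep < -1 <= shallow < -0.4 <= unaltered) or minor/major allele copy numbers
(both < 0.01 -> homozygous deletion; minor < 0.01 only -> heterozygous).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .exceptions import (
    DegenerateOutcomeError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "HMF_CODING_TERMS",
    "DELETERIOUS_TRUNCATING_TERMS",
    "DoubleHitCall",
    "parse_protein_change",
    "classify_consequence",
    "classify_cn_logratio",
    "classify_allele_cn",
    "call_double_hit",
    "association_models",
]

#: coding-consequence vocabulary used for the mutation flag
HMF_CODING_TERMS = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "stop_lost",
        "missense_variant",
        "inframe_deletion",
        "inframe_insertion",
    }
)

#: strictly protein-truncating subset used for "deleterious" calls
DELETERIOUS_TRUNCATING_TERMS = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)

#: generic splice term produced by protein-change parsing (acceptor vs donor is
#: not recoverable from "p.X###_splice"); accepted by both rule sets
_SPLICE_GENERIC = "splice_variant"

_TERM_ALIASES = {
    "frameshift": "frameshift_variant",
    "frameshift variant": "frameshift_variant",
    "stop gained": "stop_gained",
    "nonsense": "stop_gained",
    "splice acceptor variant": "splice_acceptor_variant",
    "splice donor variant": "splice_donor_variant",
    "splice variant": _SPLICE_GENERIC,
    "splice": _SPLICE_GENERIC,
    "start lost": "start_lost",
    "stop lost": "stop_lost",
    "missense": "missense_variant",
    "missense variant": "missense_variant",
    "inframe deletion": "inframe_deletion",
    "inframe insertion": "inframe_insertion",
}

_AA3 = "(?:[A-Z][a-z]{2})"
_RE_FRAMESHIFT = re.compile(r"fs\*?\d*$", re.IGNORECASE)
_RE_SPLICE = re.compile(r"_splice$", re.IGNORECASE)
_RE_STOP = re.compile(rf"^p\.(?:[A-Z]|{_AA3})\d+(?:\*|Ter)$")
_RE_MISSENSE = re.compile(rf"^p\.(?:([A-Z])\d+(?!\1)[A-Z]|({_AA3})\d+(?!\2){_AA3})$")
_RE_STARTLOST = re.compile(r"^p\.(?:M|Met)1[?A-Za-z]*$")


def normalize_consequence(term: str) -> str:
    """Map a free-text consequence label onto the controlled vocabulary.

    Returns "unknown" for anything outside it.
    """
    if term is None:
        return "unknown"
    key = str(term).strip().lower().replace("-", " ")
    canonical = key.replace(" ", "_")
    if canonical in HMF_CODING_TERMS or canonical == _SPLICE_GENERIC:
        return canonical
    return _TERM_ALIASES.get(key, "unknown")


def parse_protein_change(hgvs_p: str) -> str:
    """Infer a consequence term from an HGVS-protein style string.

    Pattern rules cover the printed variant styles: "...fs*N" -> frameshift,
    a terminal stop ("p.K810*") -> stop gained, a "_splice" suffix -> splice
    variant, "p.M1?" -> start lost, and a plain single-residue substitution ->
    missense. Never raises; anything else maps to "unknown".
    """
    if not hgvs_p or not isinstance(hgvs_p, str):
        return "unknown"
    text = hgvs_p.strip()
    if not text:
        return "unknown"
    if _RE_SPLICE.search(text):
        return _SPLICE_GENERIC
    if _RE_FRAMESHIFT.search(text):
        return "frameshift_variant"
    if _RE_STARTLOST.match(text):
        return "start_lost"
    if _RE_STOP.match(text):
        return "stop_gained"
    if _RE_MISSENSE.match(text):
        return "missense_variant"
    return "unknown"


def record_consequence(
    consequence: str | None = None, protein_change: str | None = None
) -> str:
    """Consequence term for a variant record: an explicit (normalizable) term
    wins; otherwise the protein change is parsed."""
    if consequence is not None and str(consequence).strip():
        term = normalize_consequence(consequence)
        if term != "unknown":
            return term
    return parse_protein_change(protein_change) if protein_change else "unknown"


def classify_consequence(
    consequence: str | None = None,
    protein_change: str | None = None,
    rule_set: str = "hmf_coding",
) -> bool:
    """Does a variant qualify under ``rule_set``?

    "hmf_coding" admits the full nine-term coding vocabulary;
    "deleterious_truncating" only frameshift / stop gained / splice
    acceptor-donor / start lost. A generic splice call qualifies under both.
    Unknown consequences never qualify.
    """
    term = record_consequence(consequence, protein_change)
    if rule_set == "hmf_coding":
        return term in HMF_CODING_TERMS or term == _SPLICE_GENERIC
    if rule_set == "deleterious_truncating":
        return term in DELETERIOUS_TRUNCATING_TERMS or term == _SPLICE_GENERIC
    raise InvalidInputError(f"unknown rule set {rule_set!r}")


def classify_cn_logratio(log_ratio: float) -> str:
    """Copy-number log-ratio band: deep_del < -1 <= shallow_del < -0.4 <=
    unaltered. Gains collapse into unaltered."""
    x = float(log_ratio)
    if not np.isfinite(x):
        raise InvalidInputError("log ratio must be finite")
    if x < -1.0:
        return "deep_del"
    if x < -0.4:
        return "shallow_del"
    return "unaltered"


def classify_allele_cn(minor_cn: float, major_cn: float) -> str:
    """Allele-specific deletion call: both alleles < 0.01 copies ->
    homozygous deletion; only the minor allele < 0.01 -> heterozygous."""
    if minor_cn < 0 or major_cn < 0:
        raise InvalidInputError("allele copy numbers must be non-negative")
    if minor_cn < 0.01 and major_cn < 0.01:
        return "hom_del"
    if minor_cn < 0.01:
        return "het_del"
    return "unaltered"


@dataclass(frozen=True)
class DoubleHitCall:
    """Zygosity-aware hit category for one sample/gene."""

    sample_id: str
    gene: str
    mutation_flag: bool
    deletion_flag: bool  # heterozygous deletion
    hom_del_flag: bool
    category: str  # none | mutation_only | deletion_only | double_hit | homozygous_deletion


def _cn_state(row) -> str:
    """Deletion state for one CN record; allele CN wins over log-ratio."""
    minor = row.get("minor_cn")
    major = row.get("major_cn")
    if minor is not None and major is not None and not (
        pd.isna(minor) or pd.isna(major)
    ):
        state = classify_allele_cn(float(minor), float(major))
        return {"hom_del": "deep_del", "het_del": "shallow_del"}.get(
            state, "unaltered"
        )
    lr = row.get("log_ratio")
    if lr is not None and not pd.isna(lr):
        return classify_cn_logratio(float(lr))
    raise InvalidInputError("copy-number record carries no usable representation")


def call_double_hit(
    variants: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    gene: str,
    rule_set: str = "hmf_coding",
) -> pd.DataFrame:
    """Per-sample double-hit calls for ``gene``.

    ``variants``: sample_id, gene, and protein_change and/or consequence.
    ``copy_numbers``: sample_id, gene, and log_ratio and/or minor_cn+major_cn
    (allele CN takes precedence when both are present). Any qualifying variant
    sets the mutation flag — presence, not burden, is counted. Samples
    appearing in either table are called; order of input rows is immaterial.
    """
    var = variants[variants["gene"] == gene] if len(variants) else variants
    cn = copy_numbers[copy_numbers["gene"] == gene] if len(copy_numbers) else copy_numbers

    mutated: set[str] = set()
    for r in var.to_dict("records"):
        if classify_consequence(
            r.get("consequence"), r.get("protein_change"), rule_set=rule_set
        ):
            mutated.add(str(r["sample_id"]))

    cn_state: dict[str, str] = {}
    for r in cn.to_dict("records"):
        sid = str(r["sample_id"])
        state = _cn_state(r)
        # deepest loss wins if a sample has several segments over the locus
        rank = {"unaltered": 0, "shallow_del": 1, "deep_del": 2}
        if rank[state] > rank.get(cn_state.get(sid, "unaltered"), 0):
            cn_state[sid] = state

    samples = sorted(mutated | set(cn_state))
    rows = []
    for sid in samples:
        mut = sid in mutated
        state = cn_state.get(sid, "unaltered")
        het = state == "shallow_del"
        hom = state == "deep_del"
        if hom:
            category = "homozygous_deletion"
        elif mut and het:
            category = "double_hit"
        elif mut:
            category = "mutation_only"
        elif het:
            category = "deletion_only"
        else:
            category = "none"
        rows.append(
            DoubleHitCall(
                sample_id=sid,
                gene=gene,
                mutation_flag=mut,
                deletion_flag=het,
                hom_del_flag=hom,
                category=category,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def association_models(cohort: pd.DataFrame) -> dict[str, stats.LogisticFit]:
    """Fit the two exposure-association logistic models.

    ``cohort`` needs binary columns ``exposed``, ``mutation``, ``deletion``
    (one row per patient). Model M1 regresses exposure on mutation, deletion
    and their interaction; model M2 on the double-hit indicator alone. The
    headline statistic is the interaction term of M1 (equivalently the
    double-hit term of M2). Separation or non-convergence is reported on the
    returned fits, never silently dropped.
    """
    required = {"exposed", "mutation", "deletion"}
    if not required <= set(cohort.columns):
        raise InvalidInputError(f"cohort table needs columns {sorted(required)}")
    y = cohort["exposed"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("cohort contains a single exposure class")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise InsufficientDataError("need >= 2 patients per exposure class")
    mut = cohort["mutation"].astype(float).to_numpy()
    dele = cohort["deletion"].astype(float).to_numpy()
    m1_design = pd.DataFrame(
        {"mutation": mut, "deletion": dele, "mutation_x_deletion": mut * dele}
    )
    m2_design = pd.DataFrame({"double_hit": mut * dele})
    return {
        "M1": stats.logistic_fit(m1_design, y),
        "M2": stats.logistic_fit(m2_design, y),
    }
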