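"""Worked-example reproduction: desk-scale numbers recomputed end to end.

The reference panel below holds the published study-scale inputs that are
small enough to ship as plain constants: the per-class response counts of the
ribociclib screen, the engraftment tally, and the PDX244-derivative variant
and copy-number table (eight ribociclib-resistant tumors plus the sensitive
baseline tumor 2R). ``reproduce_worked_examples`` pushes each through the
package's own operations and reports computed vs expected per item.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from . import genomics, growth

__all__ = [
    "STUDY_RESPONSE_COUNTS",
    "ENGRAFTMENT",
    "PDX244_VARIANTS",
    "PDX244_COPY_NUMBER",
    "PDX244_RESISTANT_TUMORS",
    "engraftment_rate",
    "count_deleterious_mutations",
    "reproduce_worked_examples",
]

#: mRECIST class counts over the 21 evaluable models of the ribociclib screen
STUDY_RESPONSE_COUNTS = {"CR": 1, "PR": 2, "SD": 2, "PD": 16}

#: (models established, tumor specimens implanted)
ENGRAFTMENT = (58, 473)

#: the eight ribociclib-resistant PDX244 derivatives
PDX244_RESISTANT_TUMORS = ("15L", "15R", "16L", "16R", "17L", "18R", "19L", "19R")

#: RB1 variants acquired by PDX244 derivatives (resistant tumors only)
PDX244_VARIANTS = pd.DataFrame(
    [
        {"sample_id": "16L", "gene": "RB1", "protein_change": "p.M695Nfs*26"},
        {"sample_id": "16R", "gene": "RB1", "protein_change": "p.K810*"},
        {"sample_id": "18R", "gene": "RB1", "protein_change": "p.X180_splice"},
    ]
)

#: copy-number log ratios of the PDX244 derivative panel; the sensitive
#: baseline tumor 2R carries the heterozygous RB1 loss (-0.9) and a CDKN2A
#: homozygous loss; 19L/19R deepened the RB1 loss; 15L/17L restored CDKN2A.
PDX244_COPY_NUMBER = pd.DataFrame(
    [
        {"sample_id": "2R", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "2R", "gene": "CDKN2A", "log_ratio": -4.2},
        {"sample_id": "15L", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "15L", "gene": "CDKN2A", "log_ratio": -0.4},
        {"sample_id": "15R", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "16L", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "16R", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "17L", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "17L", "gene": "CDKN2A", "log_ratio": -0.4},
        {"sample_id": "18R", "gene": "RB1", "log_ratio": -0.9},
        {"sample_id": "19L", "gene": "RB1", "log_ratio": -1.5},
        {"sample_id": "19R", "gene": "RB1", "log_ratio": -2.0},
    ]
)


def engraftment_rate(n_established: int, n_implanted: int) -> float:
    """Engraftment success rate as a percentage."""
    if n_implanted <= 0 or n_established < 0 or n_established > n_implanted:
        raise ValueError("need 0 <= established <= implanted, implanted > 0")
    return 100.0 * n_established / n_implanted


def count_deleterious_mutations(
    variants: pd.DataFrame, samples, gene: str = "RB1"
) -> int:
    """How many of ``samples`` carry a deleterious (truncating) mutation in
    ``gene`` according to the variant table."""
    sub = variants[variants["gene"] == gene]
    hit = set()
    for r in sub.to_dict("records"):
        if genomics.classify_consequence(
            r.get("consequence"), r.get("protein_change"),
            rule_set="deleterious_truncating",
        ):
            hit.add(str(r["sample_id"]))
    return sum(1 for s in samples if s in hit)


@dataclass(frozen=True)
class WorkedExampleItem:
    name: str
    computed: object
    expected: object
    passed: bool


def _item(name: str, computed, expected, eq: Callable = None) -> WorkedExampleItem:
    ok = eq(computed, expected) if eq else computed == expected
    return WorkedExampleItem(name=name, computed=computed, expected=expected, passed=ok)


def reproduce_worked_examples() -> dict[str, WorkedExampleItem]:
    """Recompute the desk-scale worked examples from the reference panel.

    Items: cohort pRR/pCB from the per-class response counts; the engraftment
    rate; the count of resistant PDX244 derivatives with deleterious RB1
    mutations; and the copy-number band calls of the RB1 log ratios. Each item
    reports computed vs expected with a pass flag; the report is
    deterministic.
    """
    items: dict[str, WorkedExampleItem] = {}

    summary = growth.cohort_summary(STUDY_RESPONSE_COUNTS)
    items["prr_pct"] = _item("prr_pct", summary.prr_pct_rounded, 14)
    items["pcb_pct"] = _item("pcb_pct", summary.pcb_pct_rounded, 24)

    items["engraftment_rate_pct"] = _item(
        "engraftment_rate_pct",
        growth.round_half_away(engraftment_rate(*ENGRAFTMENT)),
        12,
    )

    n_del = count_deleterious_mutations(
        PDX244_VARIANTS, PDX244_RESISTANT_TUMORS, gene="RB1"
    )
    items["rb1_deleterious_of_8"] = _item("rb1_deleterious_of_8", n_del, 3)

    bands = {
        lr: genomics.classify_cn_logratio(lr) for lr in (-0.9, -1.5, -2.0)
    }
    items["cn_band_calls"] = _item(
        "cn_band_calls",
        bands,
        {-0.9: "shallow_del", -1.5: "deep_del", -2.0: "deep_del"},
    )

    return items
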