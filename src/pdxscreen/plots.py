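"""Simple renderings of the standard screen figures: waterfall, spaghetti, ROC.

These are convenience views, not publication-parity figures. matplotlib is
imported lazily so the analysis modules stay importable in minimal settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def waterfall(calls: pd.DataFrame, value: str = "day_pct_change", ax=None):
    """Waterfall of per-model percent volume change, with the mRECIST band
    guides at +20 and -30 percent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    data = calls.dropna(subset=[value]).sort_values(value, ascending=False)
    ax.bar(range(len(data)), data[value], color="#7a7a7a")
    ax.axhline(20, ls="--", lw=0.8, color="k")
    ax.axhline(-30, ls="--", lw=0.8, color="k")
    ax.set_xticks(range(len(data)))
    ax.set_xticklabels(data["model_id"], rotation=90, fontsize=7)
    ax.set_ylabel("% tumor volume change")
    return ax


def spaghetti(rtv_tables: dict[str, pd.DataFrame], ax=None):
    """Relative-tumor-volume trajectories, one line per series, with the
    PD (>1.2) and PR/CR (<0.7) band guides."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, table in rtv_tables.items():
        ax.plot(table["day"], table["rtv"], marker="o", ms=3, label=label)
    ax.axhline(1.2, ls="--", lw=0.8, color="k")
    ax.axhline(0.7, ls="--", lw=0.8, color="k")
    ax.set_xlabel("day")
    ax.set_ylabel("relative tumor volume")
    if len(rtv_tables) <= 10:
        ax.legend(fontsize=7)
    return ax


def roc(result, ax=None):
    """ROC curve from a stats.ROCResult or exvivo.RocCutoffResult."""
    import matplotlib.pyplot as plt

    roc_res = getattr(result, "roc", result)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_res.fpr, roc_res.tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", lw=0.8, color="k")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc_res.auc:.3f}")
    ax.set_aspect("equal")
    return ax
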