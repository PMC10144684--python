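"""Optional figure renders: waterfall and volcano plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .association import AssociationResult, volcano_data
from .response import ResponseRecord, waterfall_order


def plot_waterfall(records: Sequence[ResponseRecord], path: str | Path, title: str = ""):
    """Bar chart of per-subject response, ordered smallest to greatest."""
    ordered = waterfall_order(list(records))
    rr = [r.response_rate for r in ordered]
    colors = ["tab:blue" if v <= 0 else "tab:red" for v in rr]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(rr)), 3.5))
    ax.bar(range(len(rr)), rr, color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(range(len(rr)))
    ax.set_xticklabels([r.subject_id for r in ordered], rotation=90, fontsize=6)
    ax.set_ylabel("response rate (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_volcano(result: AssociationResult, path: str | Path, alpha: float = 0.05):
    """rho vs -log10 p scatter, significant genes (q < alpha) highlighted."""
    data = volcano_data(result, alpha=alpha)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    sig = data["significant"]
    ax.scatter(data.loc[~sig, "rho"], data.loc[~sig, "neg_log10_p"], s=4, c="0.6")
    ax.scatter(data.loc[sig, "rho"], data.loc[sig, "neg_log10_p"], s=6, c="tab:red")
    ax.set_xlabel("Spearman rho")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{result.cohort}: {result.feature_name}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
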