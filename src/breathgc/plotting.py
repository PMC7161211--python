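"""Plot condition-wise mean signals (three coloured curves, A/B/C)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .groups import GroupSummary

_COLORS = {"A": "tab:blue", "B": "tab:orange", "C": "tab:green"}


def plot_group_means(summary: GroupSummary, dest: str | Path, filtered: bool = True) -> None:
    """Write a PNG of the per-condition mean signals over retention time."""
    curves = summary.mean_filtered if filtered else summary.mean_raw
    fig, ax = plt.subplots(figsize=(10, 4))
    for cond, curve in curves.items():
        ax.plot(summary.grid, curve, color=_COLORS.get(cond), lw=1.0,
                label=f"{cond} (n={summary.n_samples[cond]})")
    for win in summary.windows.values():
        hi = min(win.hi, summary.grid[-1])
        ax.axvspan(win.lo, hi, alpha=0.08, color="gray")
    ax.set_xlabel("retention time [min]")
    ax.set_ylabel("mean intensity [instrument units]")
    ax.set_title("Mean {} signals per condition".format("filtered" if filtered else "raw"))
    ax.legend()
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)
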