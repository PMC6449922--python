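"""Basic figure output: shared-gene-content boxplots per marker-identity bin."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .orthology import PairComparison


def bin_boxplot(
    comparisons: list[PairComparison],
    thresholds: tuple[float, ...],
    path: str | Path,
) -> None:
    """Box-and-whisker plot of percent shared genes per identity bin."""
    bins = sorted(thresholds, reverse=True)
    data = [
        [c.percent_shared for c in comparisons if c.marker_bin == t] for t in bins
    ]
    keep = [(t, d) for t, d in zip(bins, data) if d]
    if not keep:
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([d for _, d in keep], tick_labels=[f"{t:g}" for t, _ in keep])
    ax.set_xlabel("marker identity bin (%)")
    ax.set_ylabel("shared protein-coding genes (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
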