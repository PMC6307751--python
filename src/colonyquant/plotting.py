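"""Distribution plots in the style of the assay's summary figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import Ki67Summary, SizeDistribution


def plot_size_pdfs(
    dists: dict[str, SizeDistribution],
    path: str | Path,
    xlabel: str = "colony size (cells)",
    log_x: bool = True,
) -> None:
    """Probability-density curves per group, with error bars when the
    distribution carries replicate standard deviations."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, dist in dists.items():
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        if dist.density_sd is not None:
            ax.errorbar(centers, dist.density, yerr=dist.density_sd, label=name, capsize=2)
        else:
            ax.plot(centers, dist.density, marker="o", ms=3, label=name)
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ki67_cumulative(
    summaries: dict[str, Ki67Summary], path: str | Path
) -> None:
    """Cumulative frequency of the per-colony Ki-67 index, with the
    cutoff marked as a dashed line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cutoff = None
    for name, s in summaries.items():
        x = np.concatenate([[0.0], s.cumulative_x])
        # the curve starts at the fraction of index-0 colonies
        y = np.concatenate([[s.fraction_zero], s.cumulative_y])
        ax.step(x, y, where="post", label=name)
        cutoff = s.cutoff
    if cutoff is not None:
        ax.axvline(cutoff, ls="--", c="gray")
    ax.set_xlabel("Ki-67 index")
    ax.set_ylabel("cumulative frequency")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
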