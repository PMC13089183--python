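"""Static figures: per-cluster energy dot/box plots and phi histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .conformers import ClusterResult
from .geometry import GeometrySummary

__all__ = ["cluster_box_plot", "phi_histogram_plot"]


def cluster_box_plot(result: ClusterResult, path) -> None:
    """Total PIE per conformation as dots over box-whisker plots per cluster,
    annotated with the compact-letter-display letters."""
    groups = result.groups()
    ids = sorted(groups)
    fig, ax = plt.subplots(figsize=(1.2 * len(ids) + 2, 4))
    ax.boxplot([groups[c] for c in ids], positions=range(len(ids)), widths=0.5,
               showfliers=False)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for x, c in enumerate(ids):
        vals = groups[c]
        ax.plot(x + rng.uniform(-0.12, 0.12, vals.size), vals, "o", ms=3, alpha=0.6)
        if result.letters:
            ax.annotate(result.letters[c], (x, float(np.max(vals))),
                        textcoords="offset points", xytext=(0, 8), ha="center")
    ax.set_xticks(range(len(ids)), [str(c) for c in ids])
    ax.set_xlabel("cluster")
    ax.set_ylabel("total PIE (kJ/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def phi_histogram_plot(summary: GeometrySummary, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    widths = np.diff(summary.phi_bin_edges)
    ax.bar(summary.phi_bin_edges[:-1], summary.phi_counts, width=widths,
           align="edge", edgecolor="k")
    ax.axvspan(*summary.phi_range, alpha=0.15, color="green",
               label=f"optimal phi ({summary.phi_range[0]:g}-{summary.phi_range[1]:g} deg)")
    frac = summary.optimal_fraction
    title = "optimal fraction: undefined (no frames)" if frac is None else f"optimal fraction: {frac:.1f}%"
    ax.set_title(title)
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("frames")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
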