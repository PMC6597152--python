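"""Posterior visualisation: triangle (corner) plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import Posterior, posterior_summaries
from .model import PARAM_NAMES

__all__ = ["plot_triangle"]

_LABELS = {"F_over_k": "F/k", "k_over_b": "k/b (um$^2$/h)",
           "alpha": r"$\alpha$ (1/h)", "rho_unstressed": r"$\rho_u$"}


def plot_triangle(post: Posterior, path: str | Path, bins: int = 30) -> None:
    """Smoothed 1D histograms on the diagonal, 2D histograms below it.

    Dashed lines mark the mode of each smoothed 1D projection; the best
    (smallest-error) parameter sets are starred.
    """
    summ = posterior_summaries(post, bins=bins)
    n = len(PARAM_NAMES)
    fig, axes = plt.subplots(n, n, figsize=(2.4 * n, 2.4 * n))
    for i, a in enumerate(PARAM_NAMES):
        for j, b in enumerate(PARAM_NAMES):
            ax = axes[i, j]
            if j > i:
                ax.axis("off")
                continue
            if i == j:
                counts, edges = summ["hist1d"][a]
                width = np.diff(edges)
                dens = counts / max(counts.sum(), 1) / width
                ax.bar(edges[:-1], dens, width=width, align="edge",
                       color="0.8", edgecolor="none")
                xs, kde = summ["kde"][a]
                ax.plot(xs, kde, color="C0")
                ax.axvline(summ["mode"][a], ls="--", color="k", lw=0.8)
                ax.set_xlim(post.priors.bounds(a))
                ax.set_yticks([])
            else:
                H, xe, ye = summ["hist2d"][(b, a)]
                ax.pcolormesh(xe, ye, H.T, cmap="Greys")
                ax.axvline(summ["mode"][b], ls="--", color="k", lw=0.6)
                ax.axhline(summ["mode"][a], ls="--", color="k", lw=0.6)
                best = summ["best"]
                ax.plot(best[b], best[a], "*", color="C3", ms=6)
            if i == n - 1:
                ax.set_xlabel(_LABELS[b])
            else:
                ax.set_xticklabels([])
            if j == 0 and i > 0:
                ax.set_ylabel(_LABELS[a])
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
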