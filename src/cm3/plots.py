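"""Presentation-only figures: conditional Q-Q, curve overlays, yield curves.

Plotting never participates in numeric results; every function takes
already-computed artifacts and returns a matplotlib Figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_conditional_qq(qq_frame, ax=None):
    """Conditional Q-Q curves per enrichment stratum plus the null line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for s, grp in qq_frame.groupby("stratum"):
        label = "all SNPs" if s == 0 else f"bin {s}"
        style = {"ls": ":", "color": "k"} if s == 0 else {}
        ax.plot(grp["expected_neglog10p"], grp["observed_neglog10p"],
                label=label, **style)
    lim = max(qq_frame["expected_neglog10p"].max(),
              qq_frame["observed_neglog10p"].max())
    ax.plot([0, lim], [0, lim], "--", color="gray", label="null")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.legend(fontsize=7)
    return ax.figure


def plot_curve_overlays(curves: dict, model: dict | None = None, ax=None,
                        xlabel="discovery z", ylabel="mean replication z"):
    """Observed (solid) and model-predicted (dotted) curves per stratum."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("viridis")
    strata = sorted(curves)
    for i, s in enumerate(strata):
        c = curves[s]
        color = cmap(i / max(len(strata) - 1, 1))
        ok = c.nonempty
        ax.plot(c.midpoints[ok], c.value[ok], "-", color=color, lw=1,
                label=f"bin {s}")
        if model and s in model:
            mx, my = model[s]
            ax.plot(mx, my, ":", color=color, lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    return ax.figure


def plot_yield_curves(comparison, ax=None):
    """Cumulative replication rate vs number of top-ranked SNPs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curves, color, label in (
        (comparison.curves_pred, "green", "sorted by pred repl prob"),
        (comparison.curves_p, "blue", "sorted by p"),
    ):
        n = min(len(c) for c in curves)
        avg = np.mean([c[:n] for c in curves], axis=0)
        ax.plot(np.arange(1, n + 1), avg, color=color, label=label)
    ax.axhline(comparison.rate, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("number of top-ranked SNPs")
    ax.set_ylabel("cumulative replication rate")
    ax.set_xscale("log")
    ax.legend()
    return ax.figure
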