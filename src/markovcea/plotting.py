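"""Matplotlib renderings of the CE plane and sensitivity sweeps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import SweepResult, ce_plane

__all__ = ["plot_ce_plane", "plot_sweep"]


def plot_ce_plane(results, wtp: float = 15000.0, ax=None):
    """Scatter of (ΔE, ΔC) points with the willingness-to-pay line."""
    points, slope = ce_plane(results, wtp)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xs = [p.delta_effect for p in points]
    ys = [p.delta_cost for p in points]
    ax.scatter(xs, ys, s=18, alpha=0.7, zorder=3)
    span = max(abs(min(xs + [0])), abs(max(xs + [0]))) * 1.2 or 1.0
    grid = np.linspace(-span, span, 50)
    ax.plot(grid, slope * grid, "k--", lw=1, label=f"WTP = {wtp:,.0f} EUR/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental effect (QALYs)")
    ax.set_ylabel("Incremental cost (EUR)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(frameon=False)
    return ax


def plot_sweep(sweep: SweepResult, ax=None):
    """ICER across the perturbation grid against the WTP threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    g = sweep.grid
    ax.plot(g["perturbation"] * 100, g["icer"], marker="o", ms=4)
    ax.axhline(sweep.spec.wtp, color="red", ls="--", lw=1,
               label=f"WTP = {sweep.spec.wtp:,.0f} EUR/QALY")
    ax.set_xlabel(f"Perturbation of {sweep.spec.parameter_path} (%)")
    ax.set_ylabel("ICER (EUR/QALY)")
    ax.set_title("One-way sensitivity analysis")
    ax.legend(frameon=False)
    return ax
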