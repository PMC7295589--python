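"""Diagnostic figures: rose plots, PDF overlays, scan traces.

All functions take an optional matplotlib Axes and return it, so they
compose into panels; nothing here affects numeric outputs.
"""

from __future__ import annotations

import numpy as np

from .groupstats import SignificanceScanResult
from .stable import StableStepResults, pdf_overlay
from .trajectories import Trajectory, to_origin


def rose_plot(trajs, ax=None, n_select: int | None = 20, seed: int | None = 0):
    """Origin-anchored track overlay (each line is one cell's walk)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tr in to_origin(list(trajs), n_select=n_select, seed=seed):
        ax.plot(tr.x, tr.y, lw=0.8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    return ax


def pdf_overlay_plot(steps, fit: StableStepResults, ax=None, grid=None):
    """Empirical step-length density with the fitted stable PDF on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    steps = np.asarray(steps, float)
    if grid is None:
        lo, hi = np.quantile(steps, [0.001, 0.999])
        grid = np.linspace(lo, hi, 256)
    data = pdf_overlay(steps, fit, grid)
    ax.plot(data["hist_centres"], data["hist_density"], color="k",
            label="empirical")
    ax.plot(data["grid"], data["fitted"], color="0.4", label="stable fit")
    ax.set_xlabel("step length (µm)")
    ax.set_ylabel("probability density")
    ax.legend()
    return ax


def scan_plot(result: SignificanceScanResult, ax=None):
    """−log10 p over the time course with the α threshold and first hit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.table["t_min"]
    ax.plot(t, -np.log10(result.table["p_value"].clip(lower=1e-300)), marker="o", ms=3)
    ax.axhline(-np.log10(result.alpha), color="r", ls="--",
               label=f"alpha={result.alpha:g}")
    if result.earliest_significant_time is not None:
        ax.axvline(result.earliest_significant_time, color="g", ls=":",
                   label="earliest significant")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("−log10 p")
    ax.legend()
    return ax
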