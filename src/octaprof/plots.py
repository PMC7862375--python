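"""Profile and p-value figures for cohort comparisons.

One panel per metric/direction: mean patient and control profiles against
the edge-aligned offset axis (0 = APA border), and the positionwise
p-value track with the significance level and detected runs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .stats import ProfileComparisonResults

__all__ = ["plot_profiles", "plot_pvalues"]


def plot_profiles(result: ProfileComparisonResults, ax=None):
    """Mean +- SD patient and control profiles vs offset from the APA edge."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    cohort = result.model.cohort
    x = cohort.offsets_mm
    for frame, label, color in ((cohort.patient, "patients", "tab:red"),
                                (cohort.control, "controls", "tab:gray")):
        mean = frame.mean(axis=0, skipna=True).to_numpy()
        sd = frame.std(axis=0, skipna=True).to_numpy()
        ax.plot(x, mean, color=color, label=label)
        ax.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.2, lw=0)
    ax.axvline(0.0, color="k", ls=":", lw=0.8)
    for a, b in result.run_intervals_mm():
        ax.axvspan(a - 0.05, b + 0.05, color="tab:orange", alpha=0.15)
    ax.set_xlabel("offset from APA edge (mm)")
    ax.set_ylabel(f"{result.metric} fraction")
    ax.set_title(f"{result.metric} — {result.direction}")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pvalues(result: ProfileComparisonResults, ax=None):
    """Positionwise Wilcoxon p-values with the alpha line and run shading."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = result.offsets_mm
    p = np.asarray(result.p_values, dtype=float)
    ax.plot(x, p, "o-", ms=3, color="tab:blue")
    ax.axhline(result.model.alpha, color="k", ls="--", lw=0.8,
               label=f"p = {result.model.alpha}")
    ax.axvline(0.0, color="k", ls=":", lw=0.8)
    for a, b in result.run_intervals_mm():
        ax.axvspan(a - 0.05, b + 0.05, color="tab:orange", alpha=0.15)
    ax.set_yscale("log")
    ax.set_xlabel("offset from APA edge (mm)")
    ax.set_ylabel("p-value")
    ax.set_title(f"{result.metric} — {result.direction}")
    ax.legend(frameon=False, fontsize=8)
    return ax
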