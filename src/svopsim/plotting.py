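"""Simple scatter and field-map helpers for study-style figures."""

from __future__ import annotations

import numpy as np

from .analysis import PointwiseReport
from .field import VisualField


def plot_mean_threshold_scatter(mean_df, ax=None):
    """Per-test mean sensitivity, gaze device vs button device."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean_df["sap_mean_db"], mean_df["svop_mean_db"], s=18, alpha=0.8)
    lo = min(mean_df["sap_mean_db"].min(), mean_df["svop_mean_db"].min()) - 1
    hi = max(mean_df["sap_mean_db"].max(), mean_df["svop_mean_db"].max()) + 1
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel("button-test mean threshold (dB)")
    ax.set_ylabel("gaze-test mean threshold (dB)")
    return ax


def _field_map(ax, xs, ys, values, fmt="{:.2f}"):
    sc = ax.scatter(xs, ys, c=values, s=220, cmap="viridis", edgecolors="k", lw=0.3)
    for x, y, v in zip(xs, ys, values):
        if np.isfinite(v):
            ax.annotate(fmt.format(v), (x, y), ha="center", va="center", fontsize=5)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_aspect("equal")
    return sc


def plot_field(field: VisualField, ax=None):
    """Threshold map in visual-field coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    coords = field.pattern.coordinates()
    sc = _field_map(ax, coords[:, 0], coords[:, 1], field.thresholds_db, "{:.0f}")
    ax.figure.colorbar(sc, ax=ax, label="threshold (dB)")
    return ax


def plot_pointwise_map(report: PointwiseReport, ax=None):
    """Per-location Pearson r map across the test pattern."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    coords = report.pattern.coordinates()
    sc = _field_map(ax, coords[:, 0], coords[:, 1], report.r)
    ax.figure.colorbar(sc, ax=ax, label="Pearson r")
    return ax
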