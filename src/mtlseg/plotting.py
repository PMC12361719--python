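"""Quick-look plots for contours, label maps and reliability curves."""

from __future__ import annotations

import numpy as np

from .engine import LABEL_COLORS, LabelMap
from .geometry import SliceContour, arc_length_positions, point_at_arclength


def plot_slice(contour: SliceContour, intervals=None, ax=None):
    """Draw one coronal contour with its key vertices and, optionally, the
    labeled intervals of a slice (colored by region)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    pts = contour.points
    ax.plot(pts[:, 0], pts[:, 1], color="0.6", lw=1.0, zorder=1)
    for name, idx in contour.key_vertices.items():
        ax.plot(*pts[idx], "k.", ms=5)
        ax.annotate(name, pts[idx], fontsize=6, alpha=0.7)
    if intervals:
        for iv in intervals:
            ss = np.linspace(iv.s_start, iv.s_end, 40)
            seg = np.array([point_at_arclength(contour, s) for s in ss])
            color = np.array(LABEL_COLORS.get(iv.label, (0, 0, 0))) / 255.0
            ax.plot(seg[:, 0], seg[:, 1], color=color, lw=3.5,
                    zorder=2, label=f"{iv.label} ({iv.segment})")
        ax.legend(fontsize=7, loc="lower left")
    ax.set_aspect("equal")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("superior (mm)")
    ax.set_title(
        f"{contour.case_id} — {contour.slice_distance_mm:g} mm anterior"
    )
    return ax


def plot_reliability(report, ax=None):
    """Mean DSI vs landmark-perturbation sigma, one line per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, grp in report.summary.groupby("label"):
        grp = grp.sort_values("sigma_mm")
        color = np.array(LABEL_COLORS.get(str(label), (0, 0, 0))) / 255.0
        ax.errorbar(grp["sigma_mm"], grp["mean_dsi"], yerr=grp["sd_dsi"],
                    marker="o", capsize=2, label=label, color=color)
    ax.set_xlabel("landmark perturbation sigma (mm)")
    ax.set_ylabel("DSI vs unperturbed")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
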