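"""Bulls-eye plots, short-axis overlays, and cohort bar charts.

The bulls-eye flattens the 14-segment parcellation onto concentric rings:
apex at the center, valve plane outermost. The outer (valvular) half-ring is
drawn over the free-wall semicircle only, leaving the septal half open, which
mirrors the asymmetric shape of the systemic RV. Cell geometry is generated
from the same angular tables as the voxel parcellation, so figure and label
map cannot drift apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle, Wedge

from .analysis import CohortSummary
from .masks import VolumeMask
from .segments import AxisFrame, REGIONS_BY_LAYER

__all__ = ["BullseyeSpec", "BullseyeCell", "render_bullseye",
           "render_overlay", "render_bar_summary"]

logger = logging.getLogger(__name__)

#: Ring radii (relative) for apical / medial / basal / valvular rings.
_RING_RADII = (0.0, 0.3, 0.55, 0.8, 1.0)


@dataclass(frozen=True)
class BullseyeCell:
    """One drawable cell: region id, radial ring, and angular span.

    Angles are ventricular theta degrees (inferior 0°, left 90°,
    anterior 180°); the full circle is (0, 360).
    """

    region: int
    r_inner: float
    r_outer: float
    theta_start: float
    theta_end: float


@dataclass(frozen=True)
class BullseyeSpec:
    """Layout of the 14-cell bulls-eye plot.

    ``orientation_deg`` is the plot angle (degrees, counterclockwise from
    +x) at which ventricular theta 0 (the inferior direction) is drawn;
    the default puts inferior at the bottom and anterior at the top.
    """

    cmap: str = "RdBu_r"
    orientation_deg: float = 270.0
    dpi: int = 150
    annotate_directions: bool = True
    show_values: bool = True

    def cells(self) -> list:
        """The 14 cells, regions 1-14, angular spans per the parcellation."""
        r = _RING_RADII
        out = [BullseyeCell(14, r[0], r[1], 0.0, 360.0)]
        # medial quadrants centered on the four anatomical directions
        for region, start in ((10, 135.0), (11, 45.0), (12, -45.0), (13, 225.0)):
            out.append(BullseyeCell(region, r[1], r[2], start % 360.0, (start + 90.0)))
        # basal sextants bounded by the anatomical directions
        for region, start in ((4, 120.0), (5, 60.0), (6, 0.0),
                              (7, 300.0), (8, 240.0), (9, 180.0)):
            out.append(BullseyeCell(region, r[2], r[3], start, start + 60.0))
        # valvular free-wall half-ring, anterior to inferior
        for region, start in ((1, 120.0), (2, 60.0), (3, 0.0)):
            out.append(BullseyeCell(region, r[3], r[4], start, start + 60.0))
        return sorted(out, key=lambda c: c.region)

    def plot_angle(self, theta: float) -> float:
        """Ventricular theta (deg) -> matplotlib angle (deg, CCW from +x)."""
        return (self.orientation_deg + theta) % 360.0


def render_bullseye(values: Sequence[float], path=None,
                    spec: Optional[BullseyeSpec] = None,
                    vlim: Optional[float] = None,
                    title: str = "", cbar_label: str = "% of CMR EDV"):
    """Render a 14-value bulls-eye; returns (figure, axes).

    Colors use a diverging map symmetric about 0 (limits at the largest
    absolute value unless ``vlim`` is given).
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.shape != (14,):
        raise ValueError(f"expected 14 values, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("bulls-eye values must be finite")
    spec = spec or BullseyeSpec()

    vmax = float(vlim) if vlim else max(float(np.abs(values).max()), 1e-9)
    norm = plt.Normalize(-vmax, vmax)
    cmap = plt.get_cmap(spec.cmap)

    fig, ax = plt.subplots(figsize=(5, 5), dpi=spec.dpi)
    ax.set_aspect("equal")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.axis("off")
    if title:
        ax.set_title(title)

    for cell in spec.cells():
        color = cmap(norm(values[cell.region - 1]))
        if cell.region == 14:
            ax.add_patch(Circle((0, 0), cell.r_outer, facecolor=color,
                                edgecolor="black", linewidth=0.8))
            tx, ty = 0.0, 0.0
        else:
            a0 = spec.plot_angle(cell.theta_start)
            a1 = a0 + (cell.theta_end - cell.theta_start)
            ax.add_patch(Wedge((0, 0), cell.r_outer, a0, a1,
                               width=cell.r_outer - cell.r_inner,
                               facecolor=color, edgecolor="black", linewidth=0.8))
            mid = np.radians(spec.plot_angle(0.5 * (cell.theta_start + cell.theta_end)))
            rm = 0.5 * (cell.r_inner + cell.r_outer)
            tx, ty = rm * np.cos(mid), rm * np.sin(mid)
        if spec.show_values:
            ax.text(tx, ty, f"{values[cell.region - 1]:.1f}",
                    ha="center", va="center", fontsize=7)

    if spec.annotate_directions:
        for label, theta in (("I", 0.0), ("L", 90.0), ("A", 180.0), ("R", 270.0)):
            ang = np.radians(spec.plot_angle(theta))
            ax.text(1.2 * np.cos(ang), 1.2 * np.sin(ang), label,
                    ha="center", va="center", fontsize=12, fontweight="bold")

    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, fraction=0.04, pad=0.02, label=cbar_label)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig, ax


def render_overlay(cmr: VolumeMask, echo_aligned: VolumeMask, frame: AxisFrame,
                   n_planes: int = 4, path_prefix=None,
                   dpi: int = 150) -> list:
    """Short-axis contour overlays at uniformly spaced heights.

    Renders ``n_planes`` planes at the centers of equal height bands
    (h = (i + 1/2)/n). Each plane shows the CMR contour (green) with the
    aligned echo contour (red) on top. Planes intersecting neither mask are
    skipped with a notice. Returns per-plane metadata dicts including the
    in-plane cross-section areas (mm^2).
    """
    half_extent = 0.75 * frame.axis_length
    step = float(min(cmr.spacing))
    uv = np.arange(-half_extent, half_extent + step, step)
    n_side = len(uv)
    gu, gv = np.meshgrid(uv, uv, indexing="ij")

    records = []
    for i in range(n_planes):
        h = (i + 0.5) / n_planes
        center = frame.apex_origin + h * frame.axis_length * frame.long_axis
        pts = (center[None, :]
               + gu.reshape(-1, 1) * frame.inferior_axis
               + gv.reshape(-1, 1) * frame.left_axis)
        cmr_slice = cmr.sample_at(pts).reshape(n_side, n_side)
        echo_slice = echo_aligned.sample_at(pts).reshape(n_side, n_side)
        if cmr_slice.sum() == 0 and echo_slice.sum() == 0:
            logger.warning("plane h=%.3f intersects neither mask: skipped", h)
            continue

        rec = {"h": h,
               "cmr_area_mm2": float(cmr_slice.sum()) * step ** 2,
               "echo_area_mm2": float(echo_slice.sum()) * step ** 2,
               "path": None}
        if path_prefix is not None:
            fig, ax = plt.subplots(figsize=(4, 4), dpi=dpi)
            ax.set_aspect("equal")
            ax.set_title(f"short-axis plane h = {h:.2f}")
            extent = (uv[0], uv[-1], uv[0], uv[-1])
            if cmr_slice.any():
                ax.contour(cmr_slice.T, levels=[0.5], colors="green",
                           extent=extent, linewidths=1.5)
            if echo_slice.any():
                ax.contour(echo_slice.T, levels=[0.5], colors="red",
                           extent=extent, linewidths=1.5)
            ax.set_xlabel("inferior axis (mm)")
            ax.set_ylabel("left axis (mm)")
            out = Path(f"{path_prefix}_plane{i + 1}.png")
            fig.savefig(out, bbox_inches="tight")
            plt.close(fig)
            rec["path"] = str(out)
        records.append(rec)
    return records


def render_bar_summary(summary: CohortSummary, path=None, dpi: int = 150):
    """Cohort bar chart: one bar per region grouped by layer, ±SD error bars.

    Returns (figure, axes); bar heights equal the summary means exactly.
    """
    order = []
    group_labels = []
    for layer in ("apical", "medial", "basal", "valvular"):
        for r in REGIONS_BY_LAYER[layer]:
            order.append(r)
            group_labels.append(layer)

    x = []
    gap = 0.0
    prev = None
    for lab in group_labels:
        if prev is not None and lab != prev:
            gap += 1.0
        x.append(len(x) + gap)
        prev = lab

    heights = [summary.region_mean_pct[r - 1] for r in order]
    errs = [summary.region_sd_pct[r - 1] for r in order]

    fig, ax = plt.subplots(figsize=(8, 4), dpi=dpi)
    bars = ax.bar(x, heights, yerr=errs, capsize=3, color="steelblue",
                  edgecolor="black", linewidth=0.6)
    for xi, r, hgt in zip(x, order, heights):
        ax.annotate(str(r), (xi, hgt), textcoords="offset points",
                    xytext=(0, 4 if hgt >= 0 else -12), ha="center", fontsize=8)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("regional ΔEDV (% of CMR EDV)")
    seen = []
    ticks, tick_labels = [], []
    for xi, lab in zip(x, group_labels):
        if lab not in seen:
            seen.append(lab)
        ticks.append(xi)
        tick_labels.append("")
    for lab in seen:
        xs = [xi for xi, l2 in zip(x, group_labels) if l2 == lab]
        ax.annotate(lab, (float(np.mean(xs)), 0), xycoords=("data", "axes fraction"),
                    xytext=(0, -18), textcoords="offset points", ha="center")
    ax.set_xticks([])
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig, ax
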