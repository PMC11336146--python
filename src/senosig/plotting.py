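"""Publication-style figures: Kaplan-Meier plots with at-risk tables, the
significance-vs-cutoff profile, and the per-dataset KM grid.

Figures visualize numbers that already live in the report tables; nothing
is computed here beyond step-function rendering.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures go straight to files
import matplotlib.pyplot as plt
import numpy as np

from .cutoff import CutoffScanResult
from .survival import KMCurve

_COLORS = ("#000000", "#d62728", "#1f77b4", "#2ca02c")


def _step_xy(curve: KMCurve, t_max: float):
    x = np.concatenate([[0.0], curve.event_times, [t_max]])
    y = np.concatenate([[1.0], curve.survival, [curve.survival[-1] if len(curve.survival) else 1.0]])
    return x, y


def render_km(
    curves: Mapping[str, KMCurve],
    path,
    annotation: Optional[str] = None,
    ax=None,
    title: Optional[str] = None,
):
    """Step-function KM plot with at-risk counts beneath the time axis."""
    if not curves:
        raise ValueError("no curves to plot")
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 4.5))
    t_max = max(
        (float(c.event_times[-1]) if len(c.event_times) else 1.0)
        for c in curves.values()
    )
    for (label, curve), color in zip(curves.items(), _COLORS):
        x, y = _step_xy(curve, t_max)
        ax.step(x, y, where="post", label=label, color=color)
        if curve.ci_lower is not None and len(curve.event_times):
            xs = np.concatenate([[0.0], curve.event_times, [t_max]])
            lo = np.concatenate([[1.0], curve.ci_lower, [curve.ci_lower[-1]]])
            hi = np.concatenate([[1.0], curve.ci_upper, [curve.ci_upper[-1]]])
            ax.fill_between(xs, lo, hi, step="post", alpha=0.12, color=color)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("relapse-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_xlim(0, t_max * 1.02)
    if title:
        ax.set_title(title, fontsize=10)
    if len(curves) > 1:
        ax.legend(loc="lower left", fontsize=8, frameon=False)
    if annotation:
        ax.text(0.98, 0.96, annotation, transform=ax.transAxes,
                ha="right", va="top", fontsize=8)
    # number-at-risk strip under the axis
    ticks = np.linspace(0, t_max, 5)
    for k, (label, curve) in enumerate(curves.items()):
        counts = []
        for t in ticks:
            if len(curve.event_times) == 0:
                counts.append("-")
                continue
            idx = np.searchsorted(curve.event_times, t, side="left")
            counts.append(
                str(int(curve.at_risk[idx])) if idx < len(curve.at_risk) else "0"
            )
        row = "  ".join(f"{c:>5s}" for c in counts)
        ax.annotate(
            f"at risk ({label}): {row}",
            xy=(0, -0.16 - 0.06 * k),
            xycoords="axes fraction",
            fontsize=7,
            annotation_clip=False,
        )
    if own_fig:
        fig.tight_layout()
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return path


def render_scan_profile(scan: CutoffScanResult, path):
    """Significance (-log10 p) and HR vs cutoff; the minimum-p cutoff is
    circled in red."""
    table = scan.table
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["cutoff"], -np.log10(table["p"]), color="#1f77b4",
            label="-log10 p")
    ax.set_xlabel("signature score cutoff")
    ax.set_ylabel("-log10 p", color="#1f77b4")
    sel = table[table["cutoff"] == scan.selected_cutoff]
    ax.scatter(sel["cutoff"], -np.log10(sel["p"]), s=120, facecolors="none",
               edgecolors="red", linewidths=2, zorder=5, label="minimum p")
    ax2 = ax.twinx()
    ax2.plot(table["cutoff"], table["hr"], color="#7f7f7f", alpha=0.8)
    ax2.set_ylabel("HR (high vs low)", color="#7f7f7f")
    ax.axhline(-np.log10(0.05), color="k", lw=0.6, ls=":")
    fig.tight_layout()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def render_km_grid(
    panels: Sequence[tuple[str, Mapping[str, KMCurve], Optional[str]]],
    path,
    ncols: int = 3,
):
    """Grid of annotated KM panels, one per dataset."""
    if not panels:
        raise ValueError("no panels to plot")
    n = len(panels)
    ncols = min(ncols, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.2 * nrows),
                             squeeze=False)
    for k, (title, curves, annotation) in enumerate(panels):
        ax = axes[k // ncols][k % ncols]
        t_max = max(
            (float(c.event_times[-1]) if len(c.event_times) else 1.0)
            for c in curves.values()
        )
        for (label, curve), color in zip(curves.items(), _COLORS):
            x, y = _step_xy(curve, t_max)
            ax.step(x, y, where="post", label=label, color=color)
        ax.set_title(title, fontsize=9)
        ax.set_ylim(0, 1.02)
        if annotation:
            ax.text(0.98, 0.96, annotation, transform=ax.transAxes,
                    ha="right", va="top", fontsize=7)
        if k == 0:
            ax.legend(loc="lower left", fontsize=7, frameon=False)
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
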