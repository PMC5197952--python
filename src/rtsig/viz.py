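"""Profile and differential plots with above-threshold markers.

Each plot stacks one axis per requested track (coverage, mismatch
composition, arrest rate, CSA).  Positions whose track value exceeds the
configured threshold carry a marker glyph (yellow triangle) at the top of
that track's axis; with several exceeded tracks the glyphs stack per track.
Reference base letters are drawn along the x-axis only when each base gets
at least a configured number of horizontal pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import candidates as cand
from .metrics import CsaConfig

TRACKS = ("coverage", "mismatch", "arrest", "csa")
_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
_TRACK_COLUMN = {"coverage": "cov", "mismatch": "mism", "arrest": "A", "csa": "CSA"}


@dataclass
class PlotSpec:
    ref_index: int = 1
    start: int | None = None
    end: int | None = None
    tracks: tuple[str, ...] = TRACKS
    thresholds: dict = field(default_factory=dict)  # track -> marker threshold
    width: float = 1000.0   # pixels
    height: float = 600.0   # pixels
    dpi: int = 100
    legend: bool = True
    show_sequence: str = "auto"  # auto | always | never
    min_px_per_base: float = 7.0
    fmt: str = "png"

    def __post_init__(self):
        unknown = set(self.tracks) - set(TRACKS)
        if unknown:
            raise ValueError(f"unknown tracks: {sorted(unknown)}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")


def _mark_above_threshold(ax, pos, values, threshold, track):
    above = np.asarray(values, dtype=float) >= threshold
    above &= ~np.isnan(np.asarray(values, dtype=float))
    xs = np.asarray(pos)[above]
    top = ax.get_ylim()[1]
    line, = ax.plot(xs, np.full(len(xs), top), linestyle="none", marker="v",
                    markersize=8, color="gold", markeredgecolor="black",
                    label=f"{track} >= {threshold:g}", clip_on=False)
    line.set_gid(f"markers-{track}")
    return line


def _draw_sequence(ax, snap, spec):
    px_per_base = spec.width / max(len(snap), 1)
    show = spec.show_sequence == "always" or (
        spec.show_sequence == "auto" and px_per_base >= spec.min_px_per_base)
    if not show:
        return
    for p, b in zip(snap["pos"], snap["ref"]):
        ax.text(p, -0.12, b, transform=ax.get_xaxis_transform(),
                ha="center", va="top", fontsize=8, family="monospace",
                color=_BASE_COLORS.get(b, "black"))


def plot_profile(rows: pd.DataFrame, spec: PlotSpec | None = None,
                 csa_cfg: CsaConfig | None = None):
    """Render one profile region; returns the matplotlib Figure.

    ``rows`` is a profile table (already restricted to the region of
    interest, e.g. via `profiles.read_region`).
    """
    spec = spec or PlotSpec()
    snap = cand.snapshot_frame(rows, ref_index=spec.ref_index, csa_cfg=csa_cfg)
    fig, axes = plt.subplots(
        len(spec.tracks), 1, sharex=True, squeeze=False,
        figsize=(spec.width / spec.dpi, spec.height / spec.dpi), dpi=spec.dpi)
    axes = axes.ravel()
    pos = snap["pos"].to_numpy()

    for ax, track in zip(axes, spec.tracks):
        if track == "coverage":
            ax.fill_between(pos, snap["cov"], step="mid", color="#bbbbbb")
            ax.set_ylabel("coverage")
        elif track == "mismatch":
            bottom = np.zeros(len(snap))
            for b in "ACGT":
                frac = np.where(snap["ref"] == b, 0.0,
                                np.nan_to_num(snap[f"f{b}"].to_numpy(), nan=0.0))
                ax.bar(pos, frac, bottom=bottom, width=1.0,
                       color=_BASE_COLORS[b], label=b)
                bottom += frac
            ax.set_ylabel("mismatch")
            ax.set_ylim(0, max(1.0, float(np.nanmax(bottom, initial=0.0)) * 1.1))
        elif track == "arrest":
            ax.bar(pos, np.nan_to_num(snap["A"].to_numpy(), nan=0.0),
                   width=1.0, color="#444444")
            ax.set_ylabel("arrest A")
            ax.set_ylim(0, 1.05)
        elif track == "csa":
            ax.plot(pos, snap["CSA"], color="#9467bd")
            ax.set_ylabel("CSA")
        if track in spec.thresholds:
            _mark_above_threshold(ax, pos, snap[_TRACK_COLUMN[track]],
                                  spec.thresholds[track], track)
        if spec.legend and track == "mismatch":
            ax.legend(loc="upper right", fontsize=7, ncol=4)

    axes[-1].set_xlabel("position")
    if len(snap):
        _draw_sequence(axes[-1], snap, spec)
    fig.suptitle(f"reference {spec.ref_index}")
    return fig


def plot_differential(diff: pd.DataFrame, spec: PlotSpec | None = None):
    """Three-panel comparison: sample 1, sample 2, and their differences."""
    spec = spec or PlotSpec()
    fig, axes = plt.subplots(
        3, 1, sharex=True,
        figsize=(spec.width / spec.dpi, spec.height / spec.dpi), dpi=spec.dpi)
    pos = diff["pos"].to_numpy()
    for ax, tag in zip(axes[:2], ("1", "2")):
        ax.bar(pos, np.nan_to_num(diff[f"mism{tag}"].to_numpy(), nan=0.0),
               width=1.0, color="#1f77b4", label="mismatch")
        ax.plot(pos, np.nan_to_num(diff[f"A{tag}"].to_numpy(), nan=0.0),
                color="#d62728", label="arrest")
        ax.set_ylabel(f"sample {tag}")
        ax.set_ylim(0, 1.05)
    ax = axes[2]
    ax.bar(pos, np.nan_to_num(diff["d_mism"].to_numpy(), nan=0.0),
           width=1.0, color="#1f77b4", label="d_mism")
    ax.plot(pos, np.nan_to_num(diff["d_A"].to_numpy(), nan=0.0),
            color="#d62728", label="d_A")
    ax.axhline(0, color="black", linewidth=0.5)
    ax.set_ylabel("sample2 - sample1")
    ax.set_xlabel("position")
    for track, thr in spec.thresholds.items():
        col = {"mismatch": "d_mism", "arrest": "d_A", "csa": "d_CSA"}.get(track)
        if col is not None:
            _mark_above_threshold(ax, pos, np.abs(diff[col].to_numpy()), thr, track)
    if spec.legend:
        axes[0].legend(loc="upper right", fontsize=7)
    return fig


def render_plot(rows: pd.DataFrame, spec: PlotSpec, out_path,
                differential: bool = False) -> Path:
    """Render to an image file (format from the path suffix or spec.fmt)."""
    out_path = Path(out_path)
    if not out_path.suffix:
        out_path = out_path.with_suffix("." + spec.fmt)
    fig = (plot_differential if differential else plot_profile)(rows, spec)
    fig.savefig(out_path, format=out_path.suffix.lstrip("."))
    plt.close(fig)
    return out_path


def batch_plot(candidate_positions, profile_dir, ref_index: int,
               reference_length: int, out_dir, spec: PlotSpec | None = None,
               window: int = 50, block_size: int = 1000) -> list[Path]:
    """One image per candidate position, named by the position."""
    from . import profiles

    spec = spec or PlotSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in candidate_positions:
        start = max(1, int(p) - window)
        end = min(reference_length, int(p) + window)
        rows = profiles.read_region(ref_index, start, end, profile_dir,
                                    block_size=block_size)
        local = PlotSpec(**{**spec.__dict__, "ref_index": ref_index,
                            "start": start, "end": end})
        path = out_dir / f"candidate_{ref_index}_{int(p)}.{spec.fmt}"
        render_plot(rows, local, path)
        paths.append(path)
    return paths
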