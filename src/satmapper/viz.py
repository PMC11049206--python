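"""Chromosome distribution maps and repeat landscape plots.

The chromosome map mirrors the classic satellitome figure: one panel per
chromosome with two tracks — the top track shows the k most abundant
families (default 5) individually colored by rank, the bottom track pools
every remaining family.  Output is SVG by default so that re-running on
identical input produces byte-identical files (matplotlib's SVG ids are
pinned via ``svg.hashsalt`` and the creation date is suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Rectangle

from .annotator import RepeatArray

__all__ = ["MapFigureSpec", "plot_chromosome_maps", "plot_repeat_landscape"]

_PALETTE = plt.get_cmap("tab10").colors
_POOLED_COLOR = "0.45"


@dataclass
class MapFigureSpec:
    """Layout of the per-chromosome distribution figure."""

    chrom_lengths: Mapping[str, int]
    top_k: int = 5
    bar_height: float = 0.32
    track_gap: float = 0.12

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not self.chrom_lengths:
            raise ValueError("no chromosomes to draw")


def _deterministic_svg() -> dict:
    return {
        "svg.hashsalt": "satmapper",
        "svg.fonttype": "none",
    }


def split_tracks(
    annotations: Mapping[str, Sequence[RepeatArray]], top_k: int
) -> tuple[list[str], list[str]]:
    """Partition family ids into the top-k track and the pooled track.

    Families are ordered by rank when every name follows the naming
    convention (rank is embedded in the name), otherwise by total
    annotated bp.  Every family lands in exactly one track.
    """
    from .model import FAMILY_NAME_RE

    names = list(annotations)
    if names and all(FAMILY_NAME_RE.match(n) for n in names):
        ordered = sorted(names, key=lambda n: int(FAMILY_NAME_RE.match(n).group(1)))
    else:
        ordered = sorted(
            names, key=lambda n: (-sum(a.length for a in annotations[n]), n)
        )
    return ordered[:top_k], ordered[top_k:]


def plot_chromosome_maps(
    annotations: Mapping[str, Sequence[RepeatArray]],
    spec: MapFigureSpec,
    out_path: str | Path,
) -> Path:
    """Draw the two-track per-chromosome distribution figure (SVG/PNG)."""
    for name, arrays in annotations.items():
        for arr in arrays:
            if arr.chrom not in spec.chrom_lengths:
                raise ValueError(
                    f"{name}: array on unknown chromosome {arr.chrom!r}"
                )
            if arr.end > spec.chrom_lengths[arr.chrom]:
                raise ValueError(
                    f"{name}: array [{arr.start}, {arr.end}) exceeds "
                    f"{arr.chrom} length {spec.chrom_lengths[arr.chrom]}"
                )
    top, pooled = split_tracks(annotations, spec.top_k)
    chroms = list(spec.chrom_lengths)
    max_len = max(spec.chrom_lengths.values())
    with plt.rc_context(_deterministic_svg()):
        fig, axes = plt.subplots(
            len(chroms), 1,
            figsize=(9, 1.1 * len(chroms) + 0.8),
            squeeze=False,
        )
        for ax, cid in zip(axes[:, 0], chroms):
            clen = spec.chrom_lengths[cid]
            y_top = spec.bar_height + spec.track_gap
            for y0 in (y_top, 0.0):
                ax.add_patch(
                    Rectangle(
                        (0, y0), clen, spec.bar_height,
                        facecolor="white", edgecolor="black", linewidth=0.8,
                    )
                )
            for i, name in enumerate(top):
                color = _PALETTE[i % len(_PALETTE)]
                for arr in annotations[name]:
                    if arr.chrom != cid:
                        continue
                    ax.add_patch(
                        Rectangle(
                            (arr.start, y_top), arr.length, spec.bar_height,
                            facecolor=color, edgecolor="none",
                        )
                    )
            for name in pooled:
                for arr in annotations[name]:
                    if arr.chrom != cid:
                        continue
                    ax.add_patch(
                        Rectangle(
                            (arr.start, 0.0), arr.length, spec.bar_height,
                            facecolor=_POOLED_COLOR, edgecolor="none",
                        )
                    )
            ax.set_xlim(0, max_len * 1.02)
            ax.set_ylim(-0.1, 2 * spec.bar_height + spec.track_gap + 0.1)
            ax.set_yticks([])
            ax.set_ylabel(cid, rotation=0, ha="right", va="center")
            ax.spines[:].set_visible(False)
        axes[-1, 0].set_xlabel("position (bp)")
        handles = [
            Rectangle((0, 0), 1, 1, facecolor=_PALETTE[i % len(_PALETTE)])
            for i in range(len(top))
        ] + [Rectangle((0, 0), 1, 1, facecolor=_POOLED_COLOR)]
        labels = list(top) + [f"remaining ({len(pooled)} families)"]
        fig.legend(handles, labels, loc="upper right", fontsize=7, frameon=False)
        fig.tight_layout()
        out_path = Path(out_path)
        fig.savefig(out_path, metadata=_svg_metadata(out_path))
        plt.close(fig)
    return out_path


def _svg_metadata(path: Path) -> dict | None:
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    return None


def plot_repeat_landscape(
    landscape: pd.DataFrame, out_path: str | Path
) -> Path:
    """Stacked-bar repeat landscape: abundance vs. K2P divergence bin."""
    with plt.rc_context(_deterministic_svg()):
        fig, ax = plt.subplots(figsize=(8, 4))
        bottom = None
        edges = list(landscape.columns)
        width = (edges[1] - edges[0]) if len(edges) > 1 else 1.0
        for i, (name, row) in enumerate(landscape.iterrows()):
            ax.bar(
                edges, row.to_numpy(), width=width * 0.95, align="edge",
                bottom=bottom, label=name,
                color=_PALETTE[i % len(_PALETTE)],
            )
            bottom = row.to_numpy() if bottom is None else bottom + row.to_numpy()
        ax.set_xlabel("K2P divergence (%)")
        ax.set_ylabel("abundance (% of genome)")
        ax.legend(fontsize=7, frameon=False)
        fig.tight_layout()
        out_path = Path(out_path)
        fig.savefig(out_path, metadata=_svg_metadata(out_path))
        plt.close(fig)
    return out_path
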