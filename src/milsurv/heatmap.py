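"""Slide-level attention heatmaps.

Attention in this model is defined per phenotype cluster, so per-tile maps
are piecewise-constant: every tile inherits the attention weight of its
cluster. Raw weights are preserved in the export; for display they are
min-max rescaled to [0, 1] per slide. Tiles filtered out during
preprocessing are simply absent and render as transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .model import RiskOutput

__all__ = ["AttentionMap", "tile_attention", "render_heatmap",
           "load_attention_tsv"]


@dataclass
class AttentionMap:
    """Per-tile attention values for one slide."""

    slide_id: str
    entries: pd.DataFrame        # x, y, cluster, raw_attention, scaled_attention
    tile_size: int = 402
    colormap: str = "Blues"      # high attention renders blue

    def __post_init__(self) -> None:
        if self.entries.duplicated(subset=["x", "y"]).any():
            raise ValueError("duplicate tile origin in attention map")


def tile_attention(risk_output: RiskOutput, assignments: pd.DataFrame,
                   slide_id: str | None = None, tile_size: int = 402,
                   colormap: str = "Blues") -> AttentionMap:
    """Propagate cluster attention weights to the slide's tiles.

    ``assignments`` needs columns ``x, y, cluster`` (and optionally
    ``slide_id``). Raw values are the model's attention weights; scaled
    values are per-slide min-max rescaled (all 1.0 when constant, e.g. a
    single non-empty cluster).
    """
    required = {"x", "y", "cluster"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments must have columns {sorted(required)}")
    k = risk_output.attention.size
    clusters = assignments["cluster"].to_numpy(dtype=int)
    if clusters.min() < 0 or clusters.max() >= k:
        bad = clusters[(clusters < 0) | (clusters >= k)][0]
        raise ValueError(f"tile assigned to unknown cluster {bad}")
    raw = risk_output.attention[clusters]
    span = raw.max() - raw.min()
    scaled = (raw - raw.min()) / span if span > 0 else np.ones_like(raw)
    entries = pd.DataFrame({
        "x": assignments["x"].to_numpy(dtype=int),
        "y": assignments["y"].to_numpy(dtype=int),
        "cluster": clusters,
        "raw_attention": raw,
        "scaled_attention": scaled,
    })
    sid = slide_id or (str(assignments["slide_id"].iloc[0])
                       if "slide_id" in assignments else risk_output.patient_id)
    return AttentionMap(sid, entries, tile_size, colormap)


def render_heatmap(amap: AttentionMap, out_png: str | Path,
                   out_tsv: str | Path | None = None,
                   background: np.ndarray | None = None,
                   downsample: int = 50, alpha: float = 0.6) -> Path:
    """Write a rectangle-per-tile overlay PNG and a TSV of the values.

    Each kept tile becomes one ``tile_size/downsample`` pixel square at its
    grid position; positions without a tile stay fully transparent. With a
    ``background`` image (full-resolution slide) the overlay is alpha-
    blended onto its downsampled copy; sizes must agree with the tile grid.
    Rendering is pure array work, so identical inputs give bit-identical
    files.
    """
    if amap.entries.empty:
        raise ValueError("empty attention map")
    from matplotlib import colormaps

    cell = max(1, amap.tile_size // downsample)
    e = amap.entries
    gx = e["x"].to_numpy() // amap.tile_size
    gy = e["y"].to_numpy() // amap.tile_size
    W, H = (gx.max() + 1) * cell, (gy.max() + 1) * cell
    canvas = np.zeros((H, W, 4), dtype=np.uint8)
    cmap = colormaps[amap.colormap]
    colors = (np.asarray(cmap(e["scaled_attention"].to_numpy())) * 255).astype(np.uint8)
    for i in range(len(e)):
        y0, x0 = gy[i] * cell, gx[i] * cell
        canvas[y0:y0 + cell, x0:x0 + cell] = colors[i]
    if background is not None:
        bh, bw = background.shape[:2]
        if bh < (gy.max() + 1) * amap.tile_size or bw < (gx.max() + 1) * amap.tile_size:
            raise ValueError(
                f"background {bw}x{bh} smaller than the tile grid extent")
        bg = Image.fromarray(np.asarray(background, dtype=np.uint8))
        bg = bg.resize((W, H), Image.NEAREST).convert("RGBA")
        fg = Image.fromarray(canvas)
        mask = (canvas[..., 3].astype(float) * alpha).astype(np.uint8)
        fg.putalpha(Image.fromarray(mask))
        out = Image.alpha_composite(bg, fg)
    else:
        out = Image.fromarray(canvas)
    out_png = Path(out_png)
    out.save(out_png)
    if out_tsv is not None:
        tab = e.copy()
        tab.insert(0, "slide_id", amap.slide_id)
        tab.to_csv(out_tsv, sep="\t", index=False)
    return out_png


def load_attention_tsv(path: str | Path, tile_size: int = 402,
                       colormap: str = "Blues") -> AttentionMap:
    """Re-read an exported attention TSV (lossless for raw values)."""
    tab = pd.read_csv(path, sep="\t")
    sid = str(tab["slide_id"].iloc[0])
    return AttentionMap(sid, tab.drop(columns=["slide_id"]), tile_size, colormap)
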