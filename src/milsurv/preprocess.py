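"""Whole-slide tiling, background filtering and Macenko stain normalization.

A digitized slide is partitioned into non-overlapping square tiles
(402 px at 0.5 um/px by default). Tiles that are mostly white background
carry no tissue and are discarded: a pixel is "white" when all three
channels exceed ``white_threshold`` and a tile is dropped when *more than*
``max_white`` of its pixels are white (a tile at exactly the threshold is
kept).

Stain appearance varies between scanners and staining batches. Macenko
normalization works in optical-density (OD) space, where the Beer-Lambert
law makes pixel OD linear in stain concentration::

    OD = -log10((I + 1) / (I0 + 1)),        I0 = 255

The two dominant stain directions are estimated from the SVD of the tissue
OD cloud (robust angular percentiles inside the top-2 singular plane), per
pixel concentrations are recovered by non-negative least squares, rescaled
to a reference profile's robust concentration maxima, and the image is
rebuilt under the reference stain matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class InsufficientTissueError(ValueError):
    """Too few tissue (non-background) pixels to estimate stains."""


class DegenerateStainError(ValueError):
    """OD cloud is effectively rank-1: a single stain cannot be split in two."""


@dataclass
class TileImage:
    """A square RGB crop of a slide.

    ``origin`` is the 0-based (x, y) pixel offset of the top-left corner in
    the parent image; the tile covers the half-open box
    [x, x+W) x [y, y+H). ``mpp`` (micrometers per pixel) is carried as
    metadata only.
    """

    pixels: np.ndarray
    slide_id: str
    origin: tuple[int, int] = (0, 0)
    mpp: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"tile pixels must be HxWx3, got {self.pixels.shape}")

    @property
    def tile_id(self) -> str:
        x, y = self.origin
        return f"{self.slide_id}_x{x}_y{y}"


@dataclass
class StainProfile:
    """Two-stain optical-density basis plus robust concentration maxima."""

    stain_matrix: np.ndarray          # 3x2, unit-norm columns
    max_concentrations: np.ndarray    # length 2, 99th-percentile maxima
    od_base: float = 10.0
    I0: float = 255.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(f"stain_matrix column {bad} is not unit-norm (|v|={norms[bad]:.4f})")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
            "od_base": self.od_base,
            "I0": self.I0,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]),
                   d.get("od_base", 10.0), d.get("I0", 255.0))


def default_reference_profile() -> StainProfile:
    """Fixed hematoxylin/eosin reference basis (documented constants).

    Columns are the widely used H&E OD vectors; concentration maxima are
    typical robust maxima for well-stained tissue. Using a shipped constant
    makes normalization reproducible without a physical reference slide.
    """
    S = np.array([[0.65, 0.07],
                  [0.70, 0.99],
                  [0.29, 0.11]])
    S = S / np.linalg.norm(S, axis=0, keepdims=True)
    return StainProfile(S, np.array([1.9705, 1.0308]))


# ---------------------------------------------------------------------------
# tiling and background filtering
# ---------------------------------------------------------------------------

def tile_image(image: np.ndarray, slide_id: str, tile_size: int = 402,
               mpp: float = 0.5) -> list[TileImage]:
    """Partition ``image`` into a non-overlapping grid of square tiles.

    Partial edge tiles (remainder rows/columns) are dropped, never padded.
    Raises ``ValueError`` when the image is smaller than one tile.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"image {w}x{h} is smaller than one {tile_size}x{tile_size} tile")
    tiles = []
    for y in range(0, h - tile_size + 1, tile_size):
        for x in range(0, w - tile_size + 1, tile_size):
            tiles.append(TileImage(image[y:y + tile_size, x:x + tile_size],
                                   slide_id, (x, y), mpp))
    return tiles


def white_background_fraction(tile: TileImage | np.ndarray,
                              white_threshold: int = 220) -> float:
    """Fraction of pixels with all three channels strictly above threshold."""
    pixels = tile.pixels if isinstance(tile, TileImage) else np.asarray(tile)
    return float(np.all(pixels > white_threshold, axis=-1).mean())


def filter_tiles(tiles: Iterable[TileImage], max_white: float = 2 / 3,
                 white_threshold: int = 220) -> tuple[list[TileImage], pd.DataFrame]:
    """Drop tiles containing *more than* ``max_white`` white background.

    A tile with white fraction exactly equal to ``max_white`` is kept (the
    rule is strictly greater-than). Returns the kept tiles and a removal
    log with one row per input tile.
    """
    kept: list[TileImage] = []
    rows = []
    for t in tiles:
        frac = white_background_fraction(t, white_threshold)
        keep = frac <= max_white
        if keep:
            kept.append(t)
        rows.append({"slide_id": t.slide_id, "x": t.origin[0], "y": t.origin[1],
                     "white_fraction": frac, "kept": keep})
    log = pd.DataFrame(rows, columns=["slide_id", "x", "y", "white_fraction", "kept"])
    return kept, log


# ---------------------------------------------------------------------------
# optical density and Macenko normalization
# ---------------------------------------------------------------------------

def rgb_to_od(pixels: np.ndarray, I0: float = 255.0) -> np.ndarray:
    """Beer-Lambert transform; the +1 offset avoids log of zero at I=0."""
    pixels = np.asarray(pixels, dtype=float)
    return -np.log10((pixels + 1.0) / (I0 + 1.0))


def od_to_rgb(od: np.ndarray, I0: float = 255.0) -> np.ndarray:
    """Inverse transform back to 8-bit intensities (rounded, clipped)."""
    I = (I0 + 1.0) * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(I), 0, 255).astype(np.uint8)


def _nnls_two_columns(S: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a 3x2 basis, vectorized.

    For two unknowns NNLS has a closed form: take the unconstrained
    solution; if a coordinate is negative, clamp it to zero and solve the
    remaining single-stain problem.
    """
    # unconstrained: solve (S'S) c = S' od
    G = S.T @ S
    rhs = od @ S                                   # (N,2)
    c = np.linalg.solve(G, rhs.T).T                # (N,2)
    s_sq = np.diag(G)
    for j, other in ((0, 1), (1, 0)):
        neg = c[:, j] < 0
        if np.any(neg):
            c[neg, j] = 0.0
            c[neg, other] = np.maximum(rhs[neg, other] / s_sq[other], 0.0)
    return c


def estimate_stain_matrix(od_pixels: np.ndarray, beta: float = 0.15,
                          alpha_percentile: float = 1.0,
                          max_conc_percentile: float = 99.0) -> StainProfile:
    """Estimate the two dominant stain vectors from an OD pixel cloud.

    Pixels whose OD is at most ``beta`` in every channel are treated as
    background and dropped. The remaining cloud is projected onto the plane
    of its top-2 right singular vectors; the directions at the
    ``alpha_percentile`` and ``100 - alpha_percentile`` angular percentiles
    are the stain vectors. Columns are unit-normalized, sign-fixed to be
    non-negative, and ordered with the larger red-channel OD component
    first (hematoxylin-like).
    """
    od = np.asarray(od_pixels, dtype=float).reshape(-1, 3)
    tissue = od[np.any(od > beta, axis=1)]
    if tissue.shape[0] < 100:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {beta}; need >= 100")
    # top-2 singular plane of the (uncentered) OD cloud
    _, svals, vt = np.linalg.svd(tissue, full_matrices=False)
    if svals[1] <= 1e-6 * svals[0]:
        raise DegenerateStainError(
            "OD cloud is rank-1 (single stain); cannot separate two stains")
    basis = vt[:2].T                               # 3x2
    # orient the basis so projections fall on the positive side
    for j in range(2):
        if basis[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]
    proj = tissue @ basis                          # (N,2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    # inverted-CDF quantiles are invariant under sample duplication
    lo, hi = np.percentile(phi, [alpha_percentile, 100 - alpha_percentile],
                           method="inverted_cdf")
    vecs = basis @ np.stack([[np.cos(lo), np.cos(hi)],
                             [np.sin(lo), np.sin(hi)]])
    # sign-fix and unit-normalize
    for j in range(2):
        if vecs[:, j].sum() < 0:
            vecs[:, j] = -vecs[:, j]
    vecs = np.clip(vecs, 0.0, None)
    norms = np.linalg.norm(vecs, axis=0)
    if np.any(norms < 1e-12):
        raise DegenerateStainError("estimated stain vector collapsed to zero")
    vecs = vecs / norms
    if np.abs(np.dot(vecs[:, 0], vecs[:, 1])) > 1 - 1e-9:
        raise DegenerateStainError("estimated stain vectors are collinear")
    # order: larger red OD first; lexicographic tie-break
    if (vecs[0, 1], tuple(vecs[:, 1])) > (vecs[0, 0], tuple(vecs[:, 0])):
        vecs = vecs[:, ::-1]
    conc = _nnls_two_columns(vecs, tissue)
    max_c = np.percentile(conc, max_conc_percentile, axis=0)
    max_c = np.maximum(max_c, 1e-6)
    return StainProfile(vecs, max_c)


def normalize_macenko(tile: TileImage, source: StainProfile,
                      reference: StainProfile | None = None) -> TileImage:
    """Map a tile's stain concentrations onto a reference profile.

    Concentrations are solved by NNLS against the source basis, rescaled
    per stain by ``reference.max_concentrations / source.max_concentrations``
    and re-imaged under the reference basis. White pixels (zero OD, hence
    zero concentration) are fixed points.
    """
    if reference is None:
        reference = default_reference_profile()
    if np.linalg.cond(source.stain_matrix) > 1e6:
        raise ValueError("source stain matrix is ill-conditioned")
    shape = tile.pixels.shape
    od = rgb_to_od(tile.pixels, source.I0).reshape(-1, 3)
    conc = _nnls_two_columns(source.stain_matrix, od)
    conc = conc * (reference.max_concentrations / source.max_concentrations)
    od_new = conc @ reference.stain_matrix.T
    pixels = od_to_rgb(od_new, reference.I0).reshape(shape)
    return TileImage(pixels, tile.slide_id, tile.origin, tile.mpp)


def normalize_tile_auto(tile: TileImage,
                        reference: StainProfile | None = None,
                        beta: float = 0.15,
                        alpha_percentile: float = 1.0) -> TileImage:
    """Convenience: estimate the tile's own stain profile, then normalize."""
    source = estimate_stain_matrix(rgb_to_od(tile.pixels), beta, alpha_percentile)
    return normalize_macenko(tile, source, reference)


def save_tile_png(tile: TileImage, directory: str | Path) -> Path:
    """Write a tile as PNG; the filename encodes slide id and (x, y) offset."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{tile.tile_id}.png"
    Image.fromarray(tile.pixels.astype(np.uint8)).save(path)
    return path


def load_tile_png(path: str | Path, mpp: float = 0.5) -> TileImage:
    """Read a PNG written by :func:`save_tile_png` (origin parsed from name)."""
    from PIL import Image

    path = Path(path)
    stem = path.stem
    slide_id, xpart, ypart = stem.rsplit("_", 2)
    origin = (int(xpart[1:]), int(ypart[1:]))
    return TileImage(np.asarray(Image.open(path).convert("RGB")), slide_id, origin, mpp)
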