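"""Deterministic overlapping patch extraction and seamless stitching.

Training and inference operate on square patches (256 px at full scale);
an overlap of about 50% between adjacent patches avoids visible seams in
the restitched output. Stitching blends overlapping patch predictions with
a separable raised-cosine window normalized to a partition of unity, so
accumulated weights are exactly 1 at every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["TileGrid", "plan_tiles", "extract_tiles", "stitch_tiles", "raised_cosine_window"]

WINDOW_FLOOR = 1e-3


class GridError(ValueError):
    """Tile grid inconsistent with the data it is applied to."""


@dataclass
class TileGrid:
    """Layout of overlapping square tiles over an image.

    ``positions`` are (row, col) top-left anchors in anchor order;
    ``pad`` is nonzero only when the image is smaller than one tile, in
    which case a single reflect-padded tile is used.
    """

    tile_px: int
    overlap_frac: float
    positions: list[tuple[int, int]]
    image_shape: tuple[int, int]
    pad: tuple[int, int] = (0, 0)

    @property
    def stride(self) -> int:
        return max(1, round(self.tile_px * (1.0 - self.overlap_frac)))

    def __len__(self) -> int:
        return len(self.positions)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "tile_px": self.tile_px,
                    "overlap_frac": self.overlap_frac,
                    "image_shape": list(self.image_shape),
                    "positions": [list(p) for p in self.positions],
                    "pad": list(self.pad),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "TileGrid":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            tile_px=int(doc["tile_px"]),
            overlap_frac=float(doc["overlap_frac"]),
            positions=[tuple(p) for p in doc["positions"]],
            image_shape=tuple(doc["image_shape"]),
            pad=tuple(doc.get("pad", (0, 0))),
        )


def _axis_anchors(dim: int, tile_px: int, stride: int) -> list[int]:
    anchors = list(range(0, dim - tile_px + 1, stride))
    if anchors[-1] != dim - tile_px:
        anchors.append(dim - tile_px)  # clamp final anchor in-bounds
    return anchors


def plan_tiles(image_shape: tuple[int, int], tile_px: int = 256, overlap_frac: float = 0.5) -> TileGrid:
    """Plan anchors at 0, stride, 2*stride, ... with the final anchor
    clamped to ``dim - tile_px`` (deduplicated).

    Images smaller than one tile along an axis get a single reflect-padded
    tile. ``stride = round(tile_px * (1 - overlap_frac))``.
    """
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in [0, 1)")
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("image_shape must be positive")

    stride = max(1, round(tile_px * (1.0 - overlap_frac)))
    pad_h = max(0, tile_px - h)
    pad_w = max(0, tile_px - w)
    rows = [0] if pad_h else _axis_anchors(h, tile_px, stride)
    cols = [0] if pad_w else _axis_anchors(w, tile_px, stride)
    positions = [(r, c) for r in rows for c in cols]
    return TileGrid(
        tile_px=tile_px,
        overlap_frac=overlap_frac,
        positions=positions,
        image_shape=(h, w),
        pad=(pad_h, pad_w),
    )


def _padded(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    if grid.pad == (0, 0):
        return image
    pad = [(0, grid.pad[0]), (0, grid.pad[1])] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect")


def extract_tiles(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Extract tiles in anchor order; shape (n_tiles, tile, tile, ...)."""
    image = np.asarray(image)
    if tuple(image.shape[:2]) != tuple(grid.image_shape):
        raise GridError(
            f"grid planned for {grid.image_shape}, image is {image.shape[:2]}"
        )
    src = _padded(image, grid)
    t = grid.tile_px
    return np.stack([src[r : r + t, c : c + t] for r, c in grid.positions])


def raised_cosine_window(tile_px: int, floor: float = WINDOW_FLOOR) -> np.ndarray:
    """Separable 2-D raised-cosine blending window, floored at ``floor``."""
    i = np.arange(tile_px)
    w1 = 0.5 - 0.5 * np.cos(2.0 * np.pi * (i + 0.5) / tile_px)
    w1 = np.maximum(w1, floor)
    return np.outer(w1, w1)


def stitch_tiles(tiles: np.ndarray, grid: TileGrid, window: np.ndarray | None = None) -> np.ndarray:
    """Blend tiles back into an image: output(p) = sum w_t(p) tile_t(p) /
    sum w_t(p), normalization making the weights a partition of unity.

    A single covering tile reproduces itself exactly; tiles cut from one
    image stitch back to that image to floating-point precision.
    """
    tiles = np.asarray(tiles, dtype=np.float64)
    if len(tiles) != len(grid.positions):
        raise GridError(f"expected {len(grid.positions)} tiles, got {len(tiles)}")
    t = grid.tile_px
    if tiles.shape[1:3] != (t, t):
        raise GridError(f"tiles must be {t}x{t}, got {tiles.shape[1:3]}")
    if window is None:
        window = raised_cosine_window(t)
    if len(tiles) == 1:  # sole covering tile: reproduce it exactly
        return tiles[0][: grid.image_shape[0], : grid.image_shape[1]]
    extra = tiles.shape[3:]
    h = grid.image_shape[0] + grid.pad[0]
    w = grid.image_shape[1] + grid.pad[1]
    num = np.zeros((h, w) + extra)
    den = np.zeros((h, w))
    win = window if not extra else window.reshape((t, t) + (1,) * len(extra))
    for tile, (r, c) in zip(tiles, grid.positions):
        num[r : r + t, c : c + t] += win * tile
        den[r : r + t, c : c + t] += window
    den_b = den if not extra else den.reshape(den.shape + (1,) * len(extra))
    out = num / den_b
    return out[: grid.image_shape[0], : grid.image_shape[1]]


def accumulated_weights(grid: TileGrid, window: np.ndarray | None = None) -> np.ndarray:
    """Sum of *normalized* blending weights per pixel (identically 1)."""
    t = grid.tile_px
    if window is None:
        window = raised_cosine_window(t)
    h = grid.image_shape[0] + grid.pad[0]
    w = grid.image_shape[1] + grid.pad[1]
    den = np.zeros((h, w))
    for r, c in grid.positions:
        den[r : r + t, c : c + t] += window
    total = np.zeros((h, w))
    for r, c in grid.positions:
        total[r : r + t, c : c + t] += window / den[r : r + t, c : c + t]
    return total[: grid.image_shape[0], : grid.image_shape[1]]
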