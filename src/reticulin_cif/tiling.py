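"""Grayscale conversion, sliding-window tiling and tile-inclusion filters.

Tiles are square windows on a 0-based, half-open pixel grid: a tile at
(row0, col0) of size ``s`` covers rows [row0, row0+s) and columns
[col0, col0+s). Windows are enumerated row-major with a fixed stride;
remainder pixels that do not fit a full window are dropped (partial tiles
would distort area fractions). Defaults are 512-px tiles with a 256-px
stride.

A tile enters the analysis only when fat covers < 50% of its area, bone
< 1% and vessels < 10% — all strict inequalities. These filters restrict
fibrosis assessment to areas of hematopoiesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .synthetic import TissueLayout

#: Rec.601 luminance coefficients, the default RGB -> gray weighting.
REC601 = (0.299, 0.587, 0.114)

#: Strict inclusion thresholds: fat < 50%, bone < 1%, vessel < 10% of area.
FAT_MAX = 0.50
BONE_MAX = 0.01
VESSEL_MAX = 0.10


@dataclass
class Tile:
    row0: int
    col0: int
    size: int = 512
    fat_frac: float = 0.0
    bone_frac: float = 0.0
    vessel_frac: float = 0.0
    included: bool = True

    def pixels(self, image: np.ndarray) -> np.ndarray:
        return image[self.row0 : self.row0 + self.size, self.col0 : self.col0 + self.size]


@dataclass
class TileGrid:
    tiles: list[Tile]
    size: int
    stride: int
    image_shape: tuple[int, int]

    @property
    def n_rows(self) -> int:
        return grid_count(self.image_shape[0], self.size, self.stride)

    @property
    def n_cols(self) -> int:
        return grid_count(self.image_shape[1], self.size, self.stride)

    @property
    def included_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.included]

    def as_dataframe(self, sample_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "row0": t.row0,
                "col0": t.col0,
                "fat_frac": t.fat_frac,
                "bone_frac": t.bone_frac,
                "vessel_frac": t.vessel_frac,
                "included": t.included,
            }
            for t in self.tiles
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "row0",
                "col0",
                "fat_frac",
                "bone_frac",
                "vessel_frac",
                "included",
            ],
        )


def grid_count(extent: int, size: int, stride: int) -> int:
    """Number of full windows along one axis: floor((extent-size)/stride)+1."""
    if extent < size:
        return 0
    return (extent - size) // stride + 1


def to_grayscale(image: np.ndarray, weights: tuple[float, float, float] = REC601) -> np.ndarray:
    """Convert a 1- or 3-channel raster to single-channel grayscale.

    Already-grayscale input passes through unchanged. Integer input yields
    rounded integer output of the same dtype.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(np.float64) @ np.asarray(weights, dtype=np.float64)
        if np.issubdtype(image.dtype, np.integer):
            return np.clip(np.rint(gray), 0, np.iinfo(image.dtype).max).astype(image.dtype)
        return gray
    raise InvalidArgumentError(
        f"expected 1- or 3-channel image, got shape {image.shape}"
    )


def extract_grid(
    image_shape: tuple[int, int] | np.ndarray, size: int = 512, stride: int = 256
) -> TileGrid:
    """Enumerate full sliding windows row-major over the image extent.

    An image smaller than ``size`` in either axis yields an empty grid.
    """
    if size <= 0 or stride <= 0:
        raise InvalidArgumentError("size and stride must be positive")
    if isinstance(image_shape, np.ndarray):
        image_shape = image_shape.shape[:2]  # type: ignore[assignment]
    h, w = int(image_shape[0]), int(image_shape[1])
    tiles = [
        Tile(row0=i * stride, col0=j * stride, size=size)
        for i in range(grid_count(h, size, stride))
        for j in range(grid_count(w, size, stride))
    ]
    return TileGrid(tiles=tiles, size=size, stride=stride, image_shape=(h, w))


def _window_sums(mask: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Per-tile mask pixel counts via an integral image."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    s = grid.size
    out = np.empty(len(grid.tiles), dtype=np.int64)
    for k, t in enumerate(grid.tiles):
        r0, c0 = t.row0, t.col0
        out[k] = ii[r0 + s, c0 + s] - ii[r0, c0 + s] - ii[r0 + s, c0] + ii[r0, c0]
    return out


def apply_filters(
    grid: TileGrid,
    layout: TissueLayout,
    analyzable_mask: np.ndarray | None = None,
    min_analyzable: float = 1.0,
) -> TileGrid:
    """Compute mask-area fractions and set each tile's inclusion flag.

    included = (fat < 0.50) AND (bone < 0.01) AND (vessel < 0.10), strict.
    If an analyzable-tissue mask is given, tiles additionally need coverage
    >= min_analyzable of it (the default demands full coverage).
    """
    h, w = grid.image_shape
    for m in (layout.fat_mask, layout.bone_mask, layout.vessel_mask):
        if m.shape != (h, w):
            raise InvalidArgumentError(
                f"mask shape {m.shape} does not match image shape {(h, w)}"
            )
    area = float(grid.size * grid.size)
    fat = _window_sums(layout.fat_mask, grid) / area
    bone = _window_sums(layout.bone_mask, grid) / area
    vessel = _window_sums(layout.vessel_mask, grid) / area
    if analyzable_mask is not None:
        if analyzable_mask.shape != (h, w):
            raise InvalidArgumentError("analyzable mask shape mismatch")
        analyzable = _window_sums(analyzable_mask.astype(bool), grid) / area
    else:
        analyzable = np.ones(len(grid.tiles))

    tiles = []
    for k, t in enumerate(grid.tiles):
        inc = (
            fat[k] < FAT_MAX
            and bone[k] < BONE_MAX
            and vessel[k] < VESSEL_MAX
            and analyzable[k] >= min_analyzable
        )
        tiles.append(
            replace(
                t,
                fat_frac=float(fat[k]),
                bone_frac=float(bone[k]),
                vessel_frac=float(vessel[k]),
                included=bool(inc),
            )
        )
    return TileGrid(tiles=tiles, size=grid.size, stride=grid.stride, image_shape=grid.image_shape)
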