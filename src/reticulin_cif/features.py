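"""Per-sample CIF maps and fibrosis feature vectors.

A CIF map holds one score per included tile, on the tile-index grid implied
by the sliding window (excluded tiles are missing, encoded NaN). From the
map come the three per-sample fibrosis descriptors used throughout the
analysis:

* average CIF — the mean score of included tiles;
* tile distribution — fractions of tiles falling into four score bins that
  broadly correspond to the WHO fibrosis grades MF-0..MF-3 (default edges
  0, 0.25, 0.5, 0.75, 1; the last bin is closed at 1);
* heterogeneity — Shannon entropy of the bin distribution, normalized by
  ln 4 so it lies in [0, 1] (0 = all tiles in one bin, 1 = uniform).

Also here: false-color overlays (per-pixel mean of covering tile scores,
alpha-blended on the source image) and the fixed-order radar summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgumentError
from .ranker import RankingModel, preprocess_tiles, score_tiles
from .tiling import TileGrid

DEFAULT_BIN_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)

RADAR_AXES = ("avg_cif", "p0", "p1", "p2", "p3", "heterogeneity")


@dataclass(frozen=True)
class BinningScheme:
    """Five ascending cut points over [0, 1] defining four severity bins."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    labels: tuple[str, ...] = ("bin0", "bin1", "bin2", "bin3")

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) != 5 or e[0] != 0.0 or e[-1] != 1.0 or any(
            e[i] >= e[i + 1] for i in range(4)
        ):
            raise InvalidArgumentError(
                "edges must be 5 strictly increasing cut points from 0 to 1"
            )


@dataclass
class CIFMap:
    """Grid of per-tile CIF scores anchored to image coordinates.

    scores[i, j] is the score of the tile whose top-left pixel is
    (i*stride, j*stride); NaN marks excluded tiles.
    """

    scores: np.ndarray
    tile_size: int
    stride: int
    image_shape: tuple[int, int]

    @property
    def included_scores(self) -> np.ndarray:
        flat = self.scores.ravel()
        return flat[~np.isnan(flat)]

    def position(self, i: int, j: int) -> tuple[int, int]:
        return i * self.stride, j * self.stride

    def as_dataframe(self, sample_id: str = "") -> pd.DataFrame:
        rows = []
        for i in range(self.scores.shape[0]):
            for j in range(self.scores.shape[1]):
                s = self.scores[i, j]
                if np.isnan(s):
                    continue
                rows.append(
                    {
                        "sample_id": sample_id,
                        "tile_row": i,
                        "tile_col": j,
                        "row0": i * self.stride,
                        "col0": j * self.stride,
                        "score": float(s),
                    }
                )
        return pd.DataFrame(
            rows, columns=["sample_id", "tile_row", "tile_col", "row0", "col0", "score"]
        )


@dataclass
class SampleFeatureVector:
    sample_id: str
    avg_cif: float
    bin_fracs: tuple[float, float, float, float]
    heterogeneity: float
    n_tiles: int
    class_label: str = ""
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "class_label": self.class_label,
            "avg_cif": self.avg_cif,
            "p0": self.bin_fracs[0],
            "p1": self.bin_fracs[1],
            "p2": self.bin_fracs[2],
            "p3": self.bin_fracs[3],
            "heterogeneity": self.heterogeneity,
            "n_tiles": self.n_tiles,
        }
        d.update(self.extra)
        return d


def build_cif_map(model: RankingModel, grid: TileGrid, image: np.ndarray) -> CIFMap:
    """Score every included tile of the grid; excluded tiles stay NaN."""
    included = grid.included_tiles
    if not included:
        raise DataError("no included tiles: cannot build a CIF map")
    tiles = np.stack([t.pixels(image) for t in included])
    x = preprocess_tiles(tiles, input_size=model.input_size)
    scores = score_tiles(model, x)
    out = np.full((grid.n_rows, grid.n_cols), np.nan)
    for t, s in zip(included, scores):
        out[t.row0 // grid.stride, t.col0 // grid.stride] = s
    return CIFMap(
        scores=out,
        tile_size=grid.size,
        stride=grid.stride,
        image_shape=grid.image_shape,
    )


def map_from_scores(
    scores: np.ndarray, tile_size: int = 512, stride: int = 256
) -> CIFMap:
    """Wrap a raw score grid (NaN = excluded) as a CIFMap."""
    scores = np.asarray(scores, dtype=np.float64)
    h = (scores.shape[0] - 1) * stride + tile_size if scores.size else 0
    w = (scores.shape[1] - 1) * stride + tile_size if scores.size else 0
    return CIFMap(scores=scores, tile_size=tile_size, stride=stride, image_shape=(h, w))


def bin_distribution(
    cif_map: CIFMap | np.ndarray, scheme: BinningScheme | None = None
) -> np.ndarray:
    """Fractions of included tiles per severity bin; sums to 1.

    Bin k is [edge_k, edge_{k+1}); the last bin is closed so a score of
    exactly 1 counts as bin 3.
    """
    scheme = scheme if scheme is not None else BinningScheme()
    scores = cif_map.included_scores if isinstance(cif_map, CIFMap) else np.asarray(cif_map, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise DataError("empty CIF map: no included tile scores")
    edges = np.asarray(scheme.edges)
    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, 3)
    counts = np.bincount(idx, minlength=4)[:4]
    return counts / scores.size


def heterogeneity(p) -> float:
    """Normalized Shannon entropy of the bin distribution.

    H = -sum(p_k ln p_k) / ln(n_bins), with 0 ln 0 := 0, so H in [0, 1].
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < -1e-12):
        raise InvalidArgumentError("bin fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError(f"bin fractions must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def average_cif(cif_map: CIFMap | np.ndarray) -> float:
    """Arithmetic mean CIF score of included tiles."""
    scores = cif_map.included_scores if isinstance(cif_map, CIFMap) else np.asarray(cif_map, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise DataError("empty CIF map")
    return float(scores.mean())


def feature_vector(
    cif_map: CIFMap,
    sample_id: str = "",
    class_label: str = "",
    scheme: BinningScheme | None = None,
) -> SampleFeatureVector:
    """Assemble the per-sample fibrosis descriptor (avg, bins, heterogeneity)."""
    p = bin_distribution(cif_map, scheme)
    return SampleFeatureVector(
        sample_id=sample_id,
        avg_cif=average_cif(cif_map),
        bin_fracs=tuple(float(x) for x in p),  # type: ignore[arg-type]
        heterogeneity=heterogeneity(p),
        n_tiles=int(cif_map.included_scores.size),
        class_label=class_label,
    )


def radar_features(fv: SampleFeatureVector) -> tuple[tuple[str, ...], np.ndarray]:
    """Fixed-order 6-axis summary (avg, p0..p3, H) for radar plots."""
    values = np.array(
        [fv.avg_cif, *fv.bin_fracs, fv.heterogeneity], dtype=np.float64
    )
    return RADAR_AXES, values


def pixel_score_field(cif_map: CIFMap) -> np.ndarray:
    """Per-pixel mean of the scores of all tiles covering each pixel.

    Pixels covered by no included tile are NaN. With stride < tile size,
    overlapping tiles are averaged (symmetric, order-independent).
    """
    h, w = cif_map.image_shape
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    s = cif_map.tile_size
    for i in range(cif_map.scores.shape[0]):
        for j in range(cif_map.scores.shape[1]):
            v = cif_map.scores[i, j]
            if np.isnan(v):
                continue
            r0, c0 = cif_map.position(i, j)
            acc[r0 : r0 + s, c0 : c0 + s] += v
            cnt[r0 : r0 + s, c0 : c0 + s] += 1
    with np.errstate(invalid="ignore"):
        field = acc / cnt
    field[cnt == 0] = np.nan
    return field


def render_overlay(
    cif_map: CIFMap,
    image: np.ndarray,
    colormap: str = "turbo",
    alpha: float = 0.5,
) -> np.ndarray:
    """False-color heatmap of CIF scores alpha-blended onto the image.

    Excluded regions (no covering tile) keep the original pixels. alpha=0
    returns the grayscale image replicated to RGB.
    """
    from matplotlib import colormaps

    if image.shape[:2] != tuple(cif_map.image_shape):
        raise InvalidArgumentError(
            f"image shape {image.shape[:2]} does not match map extent {cif_map.image_shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError("alpha must lie in [0, 1]")
    base = np.repeat(image[:, :, None], 3, axis=2).astype(np.float64)
    if alpha == 0.0:
        return np.clip(np.rint(base), 0, 255).astype(np.uint8)
    f = pixel_score_field(cif_map)
    covered = ~np.isnan(f)
    cmap = colormaps[colormap]
    colors = cmap(np.nan_to_num(f))[:, :, :3] * 255.0
    out = base.copy()
    out[covered] = (1 - alpha) * base[covered] + alpha * colors[covered]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def features_table(fvs: list[SampleFeatureVector]) -> pd.DataFrame:
    """One CSV-ready row per sample."""
    return pd.DataFrame([fv.as_dict() for fv in fvs])
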