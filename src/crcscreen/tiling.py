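"""Tissue masking, fixed-size tiling and the 90/5/5 tile partition.

The tile grid uses the fixed 775 x 522 pixel geometry of the screening
pipeline: the grid is anchored at the image origin, partial tiles at the
right/bottom edges are dropped, and tiles without any tissue (as determined
by the tissue mask) are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import InputError, ParameterError
from .types import SlideImage, Tile, TissueMask

#: Default tile geometry (width x height in pixels).
TILE_WIDTH = 775
TILE_HEIGHT = 522

#: Background "value" (HSV brightness) above which an unsaturated pixel is glass.
_BACKGROUND_VALUE = 0.92
#: Saturation threshold used when the image is too uniform for Otsu.
_SATURATION_FALLBACK = 0.15


def compute_tissue_mask(image: SlideImage, min_object_px: int = 64) -> TissueMask:
    """Heuristic tissue/background separation on an H&E raster.

    Pixels are flagged as tissue when their HSV saturation exceeds an
    Otsu-derived threshold (stained tissue is colourful, glass is not) or
    their brightness falls below 0.92 (anything clearly darker than
    background glass). Connected components smaller than ``min_object_px``
    are removed as debris. Deterministic.
    """
    if min_object_px < 0:
        raise ParameterError("min_object_px must be >= 0")
    # HSV saturation/value computed directly (hue is not needed)
    val = image.pixels.max(axis=2)
    sat = np.where(val > 0, (val - image.pixels.min(axis=2)) / np.maximum(val, 1e-12), 0.0)
    # Otsu needs both populations present; on near-uniform saturation fall
    # back to a fixed threshold so all-glass and all-tissue images behave.
    if float(sat.max() - sat.min()) > 1e-3:
        sat_threshold = float(threshold_otsu(sat))
    else:
        sat_threshold = _SATURATION_FALLBACK
    mask = (sat > sat_threshold) | (val < _BACKGROUND_VALUE)
    if min_object_px > 1 and mask.any():
        # drop components with size < min_object_px (i.e. <= min_object_px - 1)
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask=mask, mpp_x=image.mpp_x, mpp_y=image.mpp_y)


def tile_slide(
    image: SlideImage,
    mask: TissueMask,
    min_tissue_fraction: float = 0.0,
    tile_width: int = TILE_WIDTH,
    tile_height: int = TILE_HEIGHT,
) -> list[Tile]:
    """Divide a slide into the tile grid and discard tissue-free tiles.

    A tile is retained iff ``tissue_fraction > min_tissue_fraction``; the
    default 0.0 implements the strict "any amount of tissue" rule. Tiles are
    returned in row-major order. An image smaller than one tile yields an
    empty list.
    """
    if mask.mask.shape != (image.height, image.width):
        raise InputError("tissue mask is not aligned with the image")
    if not (0.0 <= min_tissue_fraction < 1.0):
        raise ParameterError("min_tissue_fraction must lie in [0, 1)")
    if tile_width < 1 or tile_height < 1:
        raise ParameterError("tile dimensions must be positive")
    n_cols = image.width // tile_width
    n_rows = image.height // tile_height
    tiles: list[Tile] = []
    for row in range(n_rows):
        y0 = row * tile_height
        for col in range(n_cols):
            x0 = col * tile_width
            frac = float(mask.mask[y0 : y0 + tile_height, x0 : x0 + tile_width].mean())
            if frac > min_tissue_fraction:
                tiles.append(
                    Tile(
                        row=row,
                        col=col,
                        x0=x0,
                        y0=y0,
                        width=tile_width,
                        height=tile_height,
                        tissue_fraction=frac,
                    )
                )
    return tiles


def crop_tile(image: SlideImage, tile: Tile) -> np.ndarray:
    """Pixel-exact crop of one tile; raises on out-of-bounds extents."""
    if tile.x0 < 0 or tile.y0 < 0 or tile.x1 > image.width or tile.y1 > image.height:
        raise InputError(
            f"tile extent [{tile.x0},{tile.x1})x[{tile.y0},{tile.y1}) "
            f"outside image {image.width}x{image.height}"
        )
    return image.pixels[tile.y0 : tile.y1, tile.x0 : tile.x1].copy()


@dataclass(frozen=True)
class SplitAssignment:
    """A train/selection/final partition of item indices."""

    labels: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            sum(1 for l in self.labels if l == "train"),
            sum(1 for l in self.labels if l == "selection"),
            sum(1 for l in self.labels if l == "final"),
        )

    def indices(self, part: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == part], dtype=int)


def split_sizes(
    n_items: int, fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
) -> tuple[int, int, int]:
    """Partition sizes under the floor / ceil-half / floor-half rounding rule.

    ``n_train = floor(f_train * N)``; the remainder is split between the
    selection and final sets with the selection set taking the ceiling. For
    N = 73,546 at (0.90, 0.05, 0.05) this yields 66,191 / 3,678 / 3,677.
    """
    f_train, f_sel, f_final = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("fractions must be positive and sum to 1")
    if n_items < 0:
        raise ParameterError("n_items must be >= 0")
    n_train = math.floor(f_train * n_items)
    remainder = n_items - n_train
    n_sel = math.ceil(remainder * f_sel / (f_sel + f_final))
    n_final = remainder - n_sel
    return n_train, n_sel, n_final


def split_dataset(
    n_items: int,
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign items to train/selection/final partitions.

    Sizes follow :func:`split_sizes` and are independent of the seed;
    membership is a seeded uniform permutation. N = 0 yields three empty
    partitions.
    """
    n_train, n_sel, _ = split_sizes(n_items, fractions)
    perm = np.random.default_rng(seed).permutation(n_items)
    labels = np.empty(n_items, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train : n_train + n_sel]] = "selection"
    labels[perm[n_train + n_sel :]] = "final"
    return SplitAssignment(labels=tuple(labels), fractions=tuple(fractions), seed=seed)


def mask_to_png(mask: TissueMask, path) -> None:
    """Export a tissue mask as an 8-bit 0/255 PNG."""
    from .geojson_io import write_image

    arr = mask.mask.astype(float)
    write_image(path, np.stack([arr, arr, arr], axis=-1))


def tiles_to_csv(tiles: list[Tile], slide_id: str, path) -> None:
    """Write a tile manifest CSV: slide_id,row,col,x0,y0,tissue_fraction."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "slide_id": slide_id,
                "row": t.row,
                "col": t.col,
                "x0": t.x0,
                "y0": t.y0,
                "tissue_fraction": t.tissue_fraction,
            }
            for t in tiles
        ],
        columns=["slide_id", "row", "col", "x0", "y0", "tissue_fraction"],
    ).to_csv(path, index=False)
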