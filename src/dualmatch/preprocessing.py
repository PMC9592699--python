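"""CT and whole-slide-image preprocessing.

CT path: crop a radiologist-drawn rectangular ROI around the nodule,
resize it to 224 x 224 (bilinear), and stack consecutive slice triples
into 3-channel images.  WSI path: tile the slide into 224 x 224 patches
(right/bottom zero padding) and discard near-blank tiles.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import resize_bilinear

TILE = 224


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based half-open pixel bounds."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def validate(self, shape) -> None:
        h, w = shape[-2], shape[-1]
        if not (0 <= self.row_min < self.row_max <= h
                and 0 <= self.col_min < self.col_max <= w):
            raise ValueError(f"ROI {self} outside image bounds {h}x{w}")


@dataclass
class TileGrid:
    """Tiling layout of a slide: K = ceil(X/224) * ceil(Y/224) tiles."""

    x: int  # slide width
    y: int  # slide height
    coords: list = field(default_factory=list)  # (row, col) of each tile origin

    @property
    def k(self) -> int:
        return len(self.coords)


def crop_and_resize(image: np.ndarray, roi: ROISpec, size: int = TILE) -> np.ndarray:
    """Crop ``roi`` out of a (H, W) or (C, H, W) image and resize it to
    ``size`` x ``size`` with endpoint-aligned bilinear interpolation.
    Aspect distortion is allowed: the box is resized as given."""
    roi.validate(image.shape)
    crop = image[..., roi.row_min:roi.row_max, roi.col_min:roi.col_max]
    if crop.shape[-2:] == (size, size):
        return crop.copy()
    return resize_bilinear(np.asarray(crop, dtype=np.float32), size, size)


def stack_slices(slices) -> list:
    """Sliding window of three consecutive slices, stride 1: n slices
    yield n-2 three-channel images, image i = (slice i, i+1, i+2)."""
    if len(slices) < 3:
        raise ValueError("need at least 3 slices to build 3-channel images")
    arr = [np.asarray(s, dtype=np.float32) for s in slices]
    return [np.stack(arr[i:i + 3], axis=0) for i in range(len(arr) - 2)]


def tile_wsi(wsi: np.ndarray):
    """Split a (H, W) or (H, W, C) slide into 224 x 224 tiles, padding the
    right/bottom edges with zeros.  Returns (TileGrid, list of tiles)."""
    wsi = np.asarray(wsi)
    if wsi.size == 0:
        raise ValueError("empty image")
    h, w = wsi.shape[0], wsi.shape[1]
    grid = TileGrid(x=w, y=h)
    tiles = []
    for r0 in range(0, h, TILE):
        for c0 in range(0, w, TILE):
            patch = wsi[r0:r0 + TILE, c0:c0 + TILE]
            if patch.shape[0] < TILE or patch.shape[1] < TILE:
                padded = np.zeros((TILE, TILE) + wsi.shape[2:], dtype=wsi.dtype)
                padded[:patch.shape[0], :patch.shape[1]] = patch
                patch = padded
            else:
                patch = patch.copy()
            grid.coords.append((r0, c0))
            tiles.append(patch)
    # row-major loop above visits exactly ceil(h/224)*ceil(w/224) tiles
    return grid, tiles


def blank_flags(tiles, mean_threshold: float = 0.95) -> np.ndarray:
    """True where a tile is near-blank (mean intensity >= threshold)."""
    return np.array([float(np.mean(t)) >= mean_threshold for t in tiles])


def discard_blank(tiles, mean_threshold: float = 0.95) -> list:
    """Keep tiles whose mean intensity over all channels is below the
    threshold; tiles are expected normalized to [0, 1]."""
    flags = blank_flags(tiles, mean_threshold)
    return [t for t, blank in zip(tiles, flags) if not blank]


def lung_window(image_hu: np.ndarray, width: float = 1500.0,
                level: float = -600.0) -> np.ndarray:
    """Map Hounsfield units through the standard lung window (width
    1500 HU, level -600 HU) into [0, 1].  Intended for real CT input;
    synthetic data is already on [0, 1]."""
    lo = level - width / 2.0
    return np.clip((np.asarray(image_hu, dtype=np.float32) - lo) / width, 0.0, 1.0)
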