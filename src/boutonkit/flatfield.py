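"""Flat-field correction, known-layout mosaic stitching, and ratio imaging.

The illumination pattern of the excitation source is estimated from the
tiles themselves: the pixelwise average of (non-edge) tiles is smoothed
with a large Gaussian to discard structure and keep only the vignette,
then normalized to mean 1. Dividing each tile by this reference flattens
the uneven illumination while preserving the quantitative intensity
scale. Tiles are then placed on their nominal grid (registration is the
acquisition's job, not re-estimated here) with distance-to-edge blending
in the overlaps.

Ratio images divide background-subtracted green by background-subtracted
red; pixels with a non-positive denominator are masked, not infinite.
The ratio is insensitive to expression level and illumination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DegenerateInputError,
    ParameterError,
    ShapeError,
    Trace,
    common_time_base,
)

__all__ = [
    "MosaicLayout",
    "FlatFieldReference",
    "tile_positions",
    "radial_vignette",
    "build_flatfield_reference",
    "apply_flatfield",
    "stitch_grid",
    "ratio_image",
    "ratio_trace",
]

DEFAULT_KERNEL_PX = 121


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicLayout:
    """Known acquisition grid: ``rows x cols`` tiles of ``tile_shape``
    overlapping each neighbor by ``overlap_frac`` of the tile extent."""

    rows: int
    cols: int
    tile_shape: Tuple[int, int]
    overlap_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("rows and cols must be >= 1")
        if not 0 <= self.overlap_frac < 1:
            raise ParameterError("overlap_frac must be in [0, 1)")
        th, tw = self.tile_shape
        if th < 1 or tw < 1:
            raise ParameterError("tile_shape must be positive")

    def strides(self) -> Tuple[int, int]:
        th, tw = self.tile_shape
        sr = max(1, int(round(th * (1 - self.overlap_frac))))
        sc = max(1, int(round(tw * (1 - self.overlap_frac))))
        return sr, sc

    def mosaic_shape(self) -> Tuple[int, int]:
        th, tw = self.tile_shape
        sr, sc = self.strides()
        return (self.rows - 1) * sr + th, (self.cols - 1) * sc + tw

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    @classmethod
    def for_image(cls, image_shape: Tuple[int, int], rows: int, cols: int,
                  overlap_frac: float = 0.1) -> "MosaicLayout":
        """Largest square-strided layout whose mosaic fits inside
        ``image_shape`` (the generator crops the remainder)."""

        def best_tile(extent: int, n: int) -> int:
            if n == 1:
                return extent
            ub = int(np.ceil(extent / (n - (n - 1) * overlap_frac))) + 2
            for tile in range(min(ub, extent), 0, -1):
                stride = max(1, int(round(tile * (1 - overlap_frac))))
                if (n - 1) * stride + tile <= extent:
                    return tile
            raise ParameterError("image too small for the requested grid")

        th = best_tile(image_shape[0], rows)
        tw = best_tile(image_shape[1], cols)
        return cls(rows=rows, cols=cols, tile_shape=(th, tw),
                   overlap_frac=overlap_frac)


def tile_positions(layout: MosaicLayout) -> List[Tuple[int, int]]:
    """Upper-left corner of every tile, row-major order."""
    sr, sc = layout.strides()
    return [(i * sr, j * sc)
            for i in range(layout.rows) for j in range(layout.cols)]


def radial_vignette(shape: Tuple[int, int], strength: float) -> np.ndarray:
    """Radial Gaussian falloff equal to ``1 - strength`` at the corners."""
    if not 0 <= strength < 1:
        raise ParameterError("vignette strength must be in [0, 1)")
    H, W = shape
    if strength == 0:
        return np.ones((H, W))
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    rr, cols = np.mgrid[0:H, 0:W]
    d2 = (rr - cr) ** 2 + (cols - cc) ** 2
    d2_corner = cr ** 2 + cc ** 2
    return np.exp(np.log(1.0 - strength) * d2 / d2_corner)


# ---------------------------------------------------------------------------
# Flat-field reference
# ---------------------------------------------------------------------------

@dataclass
class FlatFieldReference:
    """Smooth, strictly positive illumination estimate with mean 1."""

    image: np.ndarray
    kernel_px: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if np.any(self.image <= 0):
            raise DegenerateInputError("flat-field reference must be > 0")
        if abs(self.image.mean() - 1.0) > 1e-6:
            raise ParameterError("flat-field reference must have mean 1")


def build_flatfield_reference(tiles: Sequence[np.ndarray],
                              kernel_px: int = DEFAULT_KERNEL_PX
                              ) -> FlatFieldReference:
    """Average the tiles, blur heavily, normalize to mean 1.

    The Gaussian kernel spans ``kernel_px`` pixels of support
    (sigma = kernel_px / 6), removing all structure except the shared
    illumination pattern. Edge tiles should be excluded by the caller.
    """
    tiles = [np.asarray(t, dtype=float) for t in tiles]
    if not tiles:
        raise ParameterError("need at least one tile")
    if len(tiles) == 1:
        warnings.warn("flat-field reference from a single tile",
                      stacklevel=2)
    shape = tiles[0].shape
    for t in tiles[1:]:
        if t.shape != shape:
            raise ShapeError("tiles must share a shape")
    avg = np.mean(tiles, axis=0)
    sigma = kernel_px / 6.0
    radius = (kernel_px - 1) // 2
    smooth = gaussian_filter(avg, sigma, truncate=radius / sigma,
                             mode="reflect")
    mean = smooth.mean()
    if mean <= 0 or np.any(smooth <= 0):
        raise DegenerateInputError("tiles average to a non-positive field")
    return FlatFieldReference(image=smooth / mean, kernel_px=kernel_px)


def apply_flatfield(tile: np.ndarray,
                    reference: FlatFieldReference) -> np.ndarray:
    """Divide a tile by the illumination reference."""
    tile = np.asarray(tile, dtype=float)
    if tile.shape != reference.image.shape:
        raise ShapeError(
            f"tile {tile.shape} vs reference {reference.image.shape}")
    return tile / reference.image


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch_grid(tiles: Sequence[np.ndarray],
                layout: MosaicLayout) -> np.ndarray:
    """Place tiles on the nominal grid, blending overlaps by
    distance-to-edge weights. Identical overlapping pixels reproduce the
    source image exactly."""
    tiles = [np.asarray(t, dtype=float) for t in tiles]
    if len(tiles) != layout.n_tiles:
        raise ParameterError(
            f"expected {layout.n_tiles} tiles, got {len(tiles)}")
    th, tw = layout.tile_shape
    for t in tiles:
        if t.shape != (th, tw):
            raise ShapeError("tile shape differs from layout.tile_shape")
    hat_r = np.minimum(np.arange(th) + 1, th - np.arange(th))
    hat_c = np.minimum(np.arange(tw) + 1, tw - np.arange(tw))
    weight = np.outer(hat_r, hat_c).astype(float)
    Hm, Wm = layout.mosaic_shape()
    acc = np.zeros((Hm, Wm))
    wsum = np.zeros((Hm, Wm))
    count = np.zeros((Hm, Wm), dtype=int)
    for tile, (r0, c0) in zip(tiles, tile_positions(layout)):
        acc[r0:r0 + th, c0:c0 + tw] += tile * weight
        wsum[r0:r0 + th, c0:c0 + tw] += weight
        count[r0:r0 + th, c0:c0 + tw] += 1
    mosaic = acc / wsum
    # single-coverage pixels take the tile value verbatim (no rounding)
    for tile, (r0, c0) in zip(tiles, tile_positions(layout)):
        sub = count[r0:r0 + th, c0:c0 + tw] == 1
        mosaic[r0:r0 + th, c0:c0 + tw][sub] = tile[sub]
    return mosaic


# ---------------------------------------------------------------------------
# Ratiometric images and traces
# ---------------------------------------------------------------------------

def ratio_image(green: np.ndarray, red: np.ndarray,
                bg_green: float = 0.0, bg_red: float = 0.0
                ) -> np.ma.MaskedArray:
    """Background-subtracted green/red ratio, masked where the
    denominator is non-positive."""
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ShapeError("green and red shapes differ")
    if bg_green < 0 or bg_red < 0:
        raise ParameterError("background levels must be >= 0")
    den = red - bg_red
    invalid = den <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, 0.0, (green - bg_green)
                         / np.where(invalid, 1.0, den))
    if invalid.all():
        warnings.warn("ratio image entirely masked (degenerate input)",
                      stacklevel=2)
    return np.ma.MaskedArray(ratio, mask=invalid)


def ratio_trace(green: Trace, red: Trace,
                bg_green: float = 0.0, bg_red: float = 0.0) -> Trace:
    """Pointwise green/red ratio trace after background subtraction.

    Samples with a non-positive denominator are masked in the returned
    trace rather than raising.
    """
    common_time_base([green, red])
    den = red.values - bg_red
    invalid = den <= 0
    values = np.where(invalid, np.nan,
                      (green.values - bg_green) / np.where(invalid, 1.0, den))
    return Trace(times_s=green.times_s.copy(), values=values, stage="ratio",
                 roi_id=green.roi_id,
                 mask=invalid if invalid.any() else None)
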