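"""Rectal-wall ring construction and 8x8 subimage tiling.

The rectal wall is the 2-pixel band obtained by expanding the rectum
contour inwards: ``wall = mask - erode2(mask)`` with two 3x3-square
morphological erosions.  8x8 subimages are then tiled along the wall at
1-pixel intervals, one window per wall pixel, so that the generating
wall pixel sits in the window's central 2x2 block and the window
extends 3 pixels beyond the 2-pixel band on each side of the local wall
normal (3 + 2 + 3 = 8).

Window placement rule (deterministic):

* the erosion depth d of a wall pixel is 1 (outer sub-ring) or 2;
* the outward direction along each axis is estimated from the counts of
  non-rectum pixels in the two rows (columns) above vs below the pixel
  within its 5x5 neighbourhood, out-of-image counting as outside;
* along each axis the window anchor offset is -4 when the band's other
  pixel lies between this pixel and the window edge on that side
  (depth 2 with outside on the low side, or depth 1 with outside on the
  high side) and -3 otherwise.

Anchors are de-duplicated and returned in row-major order; windows that
would cross the slice border are dropped (not padded) with the dropped
count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import SliceImage, ValidationError

logger = logging.getLogger(__name__)

WINDOW = 8
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class WallROI:
    """The 2-pixel wall ring and the filled rectum mask it came from."""

    wall_mask: np.ndarray
    source_mask: np.ndarray
    slice_index: int = 0

    def __post_init__(self):
        self.wall_mask = np.asarray(self.wall_mask, dtype=bool)
        self.source_mask = np.asarray(self.source_mask, dtype=bool)
        if self.wall_mask.shape != self.source_mask.shape:
            raise ValidationError("wall and source masks differ in shape")
        if (self.wall_mask & ~self.source_mask).any():
            raise ValidationError("wall mask is not a subset of the source mask")


@dataclass
class Subimage:
    """An 8x8 intensity window anchored at (row, col) top-left."""

    pixels: np.ndarray
    anchor: tuple[int, int]
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (WINDOW, WINDOW):
            raise ValidationError("subimage must be 8x8")


def build_wall_ring(rectum_mask: np.ndarray, slice_index: int = 0) -> WallROI:
    """2-pixel wall ring: mask minus its double 3x3-square erosion.

    If two erosions empty the mask (a tiny rectum) the wall is the whole
    mask and a warning is logged.  An empty input mask is an error.
    """
    mask = np.asarray(rectum_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValidationError("rectum mask is empty")
    eroded2 = ndimage.binary_erosion(
        mask, structure=_SQUARE3, iterations=2, border_value=0
    )
    if not eroded2.any():
        logger.warning(
            "slice %d: rectum too small for a 2-pixel inward expansion; "
            "using the whole mask as wall", slice_index
        )
    wall = mask & ~eroded2
    return WallROI(wall_mask=wall, source_mask=mask, slice_index=slice_index)


def _outward_sign(outside: np.ndarray, axis: int) -> np.ndarray:
    """Per-pixel sign of the outward direction along one axis.

    Counts outside-of-rectum pixels in the two planes below minus above
    each pixel within its 5x5 neighbourhood (out-of-image = outside);
    positive means outside lies at increasing index.
    """
    pad = np.pad(outside.astype(np.int64), 2, constant_values=1)
    h, w = outside.shape
    low = np.zeros((h, w), dtype=np.int64)   # the two planes at smaller index
    high = np.zeros((h, w), dtype=np.int64)
    for da in (-2, -1):
        for db in (-2, -1, 0, 1, 2):
            dr, dc = (da, db) if axis == 0 else (db, da)
            low += pad[2 + dr : 2 + dr + h, 2 + dc : 2 + dc + w]
    for da in (1, 2):
        for db in (-2, -1, 0, 1, 2):
            dr, dc = (da, db) if axis == 0 else (db, da)
            high += pad[2 + dr : 2 + dr + h, 2 + dc : 2 + dc + w]
    return np.sign(high - low)


def wall_window_anchors(wall: WallROI) -> np.ndarray:
    """Distinct window anchors (one per wall pixel before de-duplication),
    in row-major order, without border clipping applied."""
    mask = wall.source_mask
    wall_px = np.argwhere(wall.wall_mask)
    if wall_px.size == 0:
        return np.empty((0, 2), dtype=int)
    eroded1 = ndimage.binary_erosion(
        mask, structure=_SQUARE3, iterations=1, border_value=0
    )
    depth2 = eroded1  # wall pixels surviving one erosion are at depth 2
    outside = ~mask
    sign_r = _outward_sign(outside, axis=0)
    sign_c = _outward_sign(outside, axis=1)

    rows, cols = wall_px[:, 0], wall_px[:, 1]
    d2 = depth2[rows, cols]
    sr = sign_r[rows, cols]
    sc = sign_c[rows, cols]
    # offset -4 when the window must leave an extra slot on the low side
    off_r = np.where(((sr < 0) & d2) | ((sr > 0) & ~d2), 4, 3)
    off_c = np.where(((sc < 0) & d2) | ((sc > 0) & ~d2), 4, 3)
    anchors = np.stack([rows - off_r, cols - off_c], axis=1)
    anchors = np.unique(anchors, axis=0)  # sorted row-major
    return anchors


def tile_subimages(wall: WallROI, image: SliceImage | np.ndarray) -> list[Subimage]:
    """8x8 subimages tiled along the wall ring at 1-pixel intervals.

    Returns one window per distinct anchor; windows that would cross the
    slice border are dropped with a logged count.  An empty wall yields
    an empty list.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if pixels.shape != wall.wall_mask.shape:
        raise ValidationError("wall and image dimensions differ")
    anchors = wall_window_anchors(wall)
    if anchors.shape[0] == 0:
        return []
    h, w = pixels.shape
    ok = (
        (anchors[:, 0] >= 0)
        & (anchors[:, 1] >= 0)
        & (anchors[:, 0] + WINDOW <= h)
        & (anchors[:, 1] + WINDOW <= w)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "slice %d: dropped %d window(s) crossing the slice border",
            wall.slice_index, dropped,
        )
    return [
        Subimage(
            pixels=pixels[r : r + WINDOW, c : c + WINDOW],
            anchor=(int(r), int(c)),
            slice_index=wall.slice_index,
        )
        for r, c in anchors[ok]
    ]


def subimage_stack(subimages: list[Subimage]) -> np.ndarray:
    """Stack subimage pixel grids into an (n, 8, 8) array."""
    if not subimages:
        return np.empty((0, WINDOW, WINDOW))
    return np.stack([s.pixels for s in subimages])
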