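"""Mapping between the physical partition grid and image pixel coordinates.

Shared by the synthetic renderer and the image-analysis stage so both sides
agree on where partition patches live.  Images are indexed (row, col),
0-based, origin top-left; centres are stored in pixel units as floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ArrayGeometry


@dataclass(frozen=True)
class PixelLayout:
    """Pixel-space layout of one partition array.

    Parameters
    ----------
    geometry : ArrayGeometry
        Physical grid.
    pixel_pitch : float
        µm per pixel.  The default (10 µm/px) renders the 65 µm well as a
        7 × 9 px patch, the smallest size at which mean-intensity extraction
        is stable.
    margin_px : int
        Blank border around the grid.
    offset : (dx, dy)
        Translation of the whole grid in pixels (x = columns, y = rows).
    """

    geometry: ArrayGeometry
    pixel_pitch: float = 10.0
    margin_px: int = 20
    offset: tuple[float, float] = (0.0, 0.0)

    @property
    def patch_half(self) -> tuple[int, int]:
        """Half-extent (hx, hy) of a partition patch in pixels; patch = 2h+1."""
        hx = max(1, int(self.geometry.wells.x / self.pixel_pitch / 2))
        hy = max(1, int(self.geometry.wells.y / self.pixel_pitch / 2))
        return hx, hy

    @property
    def pitch_px(self) -> tuple[float, float]:
        return (self.geometry.pitch_x / self.pixel_pitch,
                self.geometry.pitch_y / self.pixel_pitch)

    @property
    def image_shape(self) -> tuple[int, int]:
        hx, hy = self.patch_half
        px, py = self.pitch_px
        width = math.ceil(2 * self.margin_px + 2 * hx + (self.geometry.cols - 1) * px) + 1
        height = math.ceil(2 * self.margin_px + 2 * hy + (self.geometry.rows - 1) * py) + 1
        return height, width

    def grid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) index arrays in row-major partition order."""
        g = self.geometry
        rows = np.repeat(np.arange(g.rows), g.cols)
        cols = np.tile(np.arange(g.cols), g.rows)
        return rows, cols

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Partition centre coordinates (cx, cy) in pixels, row-major order."""
        hx, hy = self.patch_half
        px, py = self.pitch_px
        rows, cols = self.grid_indices()
        cx = self.margin_px + hx + cols * px + self.offset[0]
        cy = self.margin_px + hy + rows * py + self.offset[1]
        return cx, cy

    def patch_origins(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer top-left corner (x0, y0) of each patch window."""
        hx, hy = self.patch_half
        cx, cy = self.centers()
        x0 = np.rint(cx).astype(int) - hx
        y0 = np.rint(cy).astype(int) - hy
        return x0, y0

    def template(self) -> np.ndarray:
        """Binary image with 1 inside every patch window — the ideal grid."""
        hx, hy = self.patch_half
        img = np.zeros(self.image_shape, dtype=float)
        x0, y0 = self.patch_origins()
        xs = x0[:, None] + np.arange(2 * hx + 1)
        ys = y0[:, None] + np.arange(2 * hy + 1)
        img[ys[:, :, None], xs[:, None, :]] = 1.0
        return img

    def patch_mask(self) -> np.ndarray:
        """Boolean mask of all patch pixels (True inside patches)."""
        return self.template() > 0
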