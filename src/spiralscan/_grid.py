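"""Shared raster-grid geometry.

One convention, used everywhere: world coordinates are FOV-centred
millimetres with x rightward and y upward; image row 0 is at the top,
x maps to columns and y to rows.  Pixel (i, j) of an (ny, nx) grid with
pixel size ``d`` covers the half-open cell

    x in [x0 + j*d, x0 + (j+1)*d),   y in (y_top - (i+1)*d, y_top - i*d]

with x0 = -nx*d/2 and y_top = +ny*d/2.  Points landing exactly on the
far (right / bottom) edge are assigned to the last pixel so that the
closed disk r <= R of an inscribed FOV bins without loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "grid_half_extent",
    "world_to_index",
    "world_to_fractional_index",
    "pixel_center_coords",
    "pixel_radius_map",
]


def grid_half_extent(shape: tuple[int, int], pixel_size: float) -> tuple[float, float]:
    """Half-width and half-height (mm) of the grid extent (x then y)."""
    ny, nx = shape
    return nx * pixel_size / 2.0, ny * pixel_size / 2.0


def world_to_index(x, y, shape: tuple[int, int], pixel_size: float):
    """Map world (x, y) to integer pixel indices (i, j); no bounds check."""
    ny, nx = shape
    hx, hy = grid_half_extent(shape, pixel_size)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    j = np.floor((x + hx) / pixel_size).astype(np.int64)
    i = np.floor((hy - y) / pixel_size).astype(np.int64)
    # closed outer boundary: exact far-edge hits belong to the last pixel
    j = np.where((j == nx) & np.isclose(x, hx), nx - 1, j)
    i = np.where((i == ny) & np.isclose(y, -hy), ny - 1, i)
    return i, j


def world_to_fractional_index(x, y, shape: tuple[int, int], pixel_size: float):
    """Map world (x, y) to fractional (row, col) with integers at pixel centres."""
    ny, nx = shape
    hx, hy = grid_half_extent(shape, pixel_size)
    col = (np.asarray(x, dtype=float) + hx) / pixel_size - 0.5
    row = (hy - np.asarray(y, dtype=float)) / pixel_size - 0.5
    return row, col


def pixel_center_coords(shape: tuple[int, int], pixel_size: float):
    """World coordinates of pixel centres as meshgrids (X, Y), shape ``shape``."""
    ny, nx = shape
    hx, hy = grid_half_extent(shape, pixel_size)
    xc = -hx + (np.arange(nx) + 0.5) * pixel_size
    yc = hy - (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(xc, yc)


def pixel_radius_map(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Distance (mm) of every pixel centre from the grid centre."""
    X, Y = pixel_center_coords(shape, pixel_size)
    return np.hypot(X, Y)
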