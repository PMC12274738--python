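"""Sampling homogeneity and energy deposition of a scan trajectory.

Binning the pulse positions of a frame onto the reconstruction grid gives
a per-pixel pulse count; because every pulse deposits (nominally) the same
energy, the count map is also a relative map of laser energy deposition.
The *energy factor* compresses it for display and comparison:

    E = log10(counts + 1) / max(log10(counts + 1))

so E is in [0, 1] and is exactly 0 where no pulse landed.  Two further
summaries quantify centre/edge balance:

* central pulse fraction — the percentage of pulses inside the central
  disk holding a given fraction ``f`` of the scan area (radius
  ``R * sqrt(f)``); and
* radial fill profile — per-annulus fraction of pixels hit at least once,
  plus mean counts per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._grid import grid_half_extent, pixel_radius_map, world_to_index
from .trajectory import ScanTrajectory

__all__ = [
    "SamplingDensityMap",
    "density_map",
    "central_pulse_fraction",
    "central_fraction_table",
    "radial_fill_profile",
]


@dataclass
class SamplingDensityMap:
    """Per-pixel pulse counts and the derived energy-factor raster."""

    counts: np.ndarray
    pixel_size: float
    energy_factor: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_tiff(self, counts_path: str | Path, energy_path: str | Path | None = None) -> None:
        tifffile.imwrite(str(counts_path), self.counts.astype(np.float32))
        if energy_path is not None:
            tifffile.imwrite(str(energy_path), self.energy_factor.astype(np.float32))


def _energy_factor(counts: np.ndarray) -> np.ndarray:
    e = np.log10(counts.astype(float) + 1.0)
    m = e.max()
    return e / m if m > 0 else e


def density_map(
    traj: ScanTrajectory,
    grid_shape: int | tuple[int, int] = 512,
    pixel_size: float | None = None,
) -> SamplingDensityMap:
    """Bin pulse positions into pixels (half-open cells, closed outer edge).

    ``pixel_size`` defaults to ``fov_diameter / grid``, so the FOV circle is
    inscribed in the grid.  Every pulse must land inside the grid extent;
    the first offending pulse index is reported otherwise.
    """
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    if pixel_size is None:
        pixel_size = traj.params.fov_diameter / grid_shape[1]
    ny, nx = grid_shape
    i, j = world_to_index(traj.x, traj.y, grid_shape, pixel_size)
    bad = (i < 0) | (i >= ny) | (j < 0) | (j >= nx)
    if bad.any():
        k = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"pulse {k} at ({traj.x[k]:.6g}, {traj.y[k]:.6g}) mm lies outside "
            f"the {ny}x{nx} grid of pixel size {pixel_size:.6g} mm"
        )
    counts = np.zeros(grid_shape, dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return SamplingDensityMap(
        counts=counts, pixel_size=pixel_size, energy_factor=_energy_factor(counts)
    )


def central_pulse_fraction(traj: ScanTrajectory, area_fraction: float) -> float:
    """Percentage of pulses inside the central disk of the given area fraction.

    A disk holding area fraction ``f`` of the circular FOV has radius
    ``R * sqrt(f)``.  Continuous-limit values: ``100*sqrt(f)`` for AS,
    ``100*f`` for FS, and their mean for the compound frame.
    """
    if not 0.0 < area_fraction < 1.0:
        raise ValueError("area_fraction must lie strictly between 0 and 1")
    rho = traj.params.radius * np.sqrt(area_fraction)
    return 100.0 * float(np.count_nonzero(traj.r <= rho)) / traj.n_points


def central_fraction_table(
    trajectories: dict[str, ScanTrajectory],
    area_fractions: tuple[float, ...] = (1.0 / 256.0, 1.0 / 64.0),
) -> pd.DataFrame:
    """Central-pulse-fraction summary for several trajectories (percent)."""
    rows = [
        {
            "pattern": name,
            "area_fraction": f,
            "pulse_percent": central_pulse_fraction(traj, f),
        }
        for name, traj in trajectories.items()
        for f in area_fractions
    ]
    return pd.DataFrame(rows)


def radial_fill_profile(dmap: SamplingDensityMap, n_bins: int = 16) -> pd.DataFrame:
    """Filled-pixel fraction and mean counts in equal-width radial annuli.

    Annuli span [0, R] where R is the inscribed-circle radius of the grid;
    pixels outside the FOV circle are ignored.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    hx, hy = grid_half_extent(dmap.grid_shape, dmap.pixel_size)
    radius = min(hx, hy)
    rmap = pixel_radius_map(dmap.grid_shape, dmap.pixel_size)
    edges = np.linspace(0.0, radius, n_bins + 1)
    rows = []
    for b in range(n_bins):
        sel = (rmap >= edges[b]) & (rmap < edges[b + 1])
        n_px = int(np.count_nonzero(sel))
        c = dmap.counts[sel]
        rows.append(
            {
                "annulus_index": b,
                "r_inner_mm": edges[b],
                "r_outer_mm": edges[b + 1],
                "fill_fraction": float(np.count_nonzero(c) / n_px) if n_px else np.nan,
                "mean_counts": float(c.mean()) if n_px else np.nan,
            }
        )
    return pd.DataFrame(rows)
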