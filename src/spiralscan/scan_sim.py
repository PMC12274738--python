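"""Per-pulse acquisition simulation, image gridding, and rigid stitching.

``acquire`` samples a phantom's absorption raster at every pulse position
of a scan trajectory (bilinear interpolation, since the optical focus
lands between pixel centres), adds Gaussian amplitude noise and clips at
zero.  ``reconstruct`` grids the scattered pulse records back onto pixels:
``bin_mean`` averages the samples landing in each pixel and leaves
never-sampled pixels at zero with a false fill flag (the raw image of a
sparse scan); ``nearest``/``linear`` additionally fill the gaps by
scattered interpolation.  Adjacent fields of view are mosaicked with
landmark-based rigid registration (rotation + translation, no scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import interpolate, ndimage

from ._grid import (
    grid_half_extent,
    pixel_center_coords,
    world_to_fractional_index,
    world_to_index,
)
from .phantom import VascularPhantom
from .trajectory import ScanTrajectory

__all__ = [
    "PulseRecordSet",
    "ReconstructedImage",
    "RigidTransform2D",
    "PointScan",
    "pixel_center_scan",
    "acquire",
    "reconstruct",
    "fit_rigid",
    "stitch",
]


@dataclass
class PointScan:
    """A bare list of pulse positions/times; stand-in for a ScanTrajectory."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.x)


def pixel_center_scan(shape: tuple[int, int], pixel_size: float, prf: float = 200_000.0) -> PointScan:
    """Dense raster visiting every pixel centre once (for full-sampling runs)."""
    X, Y = pixel_center_coords(shape, pixel_size)
    n = X.size
    return PointScan(x=X.ravel(), y=Y.ravel(), t=np.arange(n) / prf)


@dataclass
class PulseRecordSet:
    """Per-pulse records: time, position, wavelength tag and amplitude."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    wavelength: np.ndarray  # nm, int
    amplitude: np.ndarray
    noise_sigma: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "wavelength", "amplitude"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"record field {name!r} length mismatch")
        if (self.amplitude < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_records(self) -> int:
        return len(self.t)

    def wavelengths(self) -> np.ndarray:
        return np.unique(self.wavelength)

    def select(self, wavelength: int) -> "PulseRecordSet":
        m = self.wavelength == wavelength
        if not m.any():
            raise ValueError(f"no records at {wavelength} nm")
        return PulseRecordSet(
            t=self.t[m], x=self.x[m], y=self.y[m],
            wavelength=self.wavelength[m], amplitude=self.amplitude[m],
            noise_sigma=self.noise_sigma, rng_seed=self.rng_seed,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "wavelength_nm": self.wavelength,
                "amplitude": self.amplitude,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PulseRecordSet":
        df = pd.read_csv(path)
        return cls(
            t=df["t_s"].to_numpy(),
            x=df["x_mm"].to_numpy(),
            y=df["y_mm"].to_numpy(),
            wavelength=df["wavelength_nm"].to_numpy(dtype=int),
            amplitude=df["amplitude"].to_numpy(),
        )


@dataclass
class ReconstructedImage:
    """Gridded amplitude raster with a sampled-pixel mask."""

    pixels: np.ndarray
    fill_mask: np.ndarray
    pixel_size: float
    wavelength: int | None = None
    interpolated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels.astype(np.float32))


def _bilinear(raster: np.ndarray, x, y, pixel_size: float) -> np.ndarray:
    row, col = world_to_fractional_index(x, y, raster.shape, pixel_size)
    return ndimage.map_coordinates(raster.astype(float), [row, col], order=1, mode="nearest")


def acquire(
    phantom: VascularPhantom,
    traj: ScanTrajectory | PointScan,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    dual_wavelength: bool = False,
    wavelength: int = 532,
    lag_pulses: int = 0,
) -> PulseRecordSet:
    """Simulate pulse-by-pulse acquisition of a phantom along a trajectory.

    Amplitude = bilinear sample of mu_a(lambda) at the pulse position plus
    Gaussian noise of scale ``noise_sigma``, clipped at zero.  In
    dual-wavelength mode both lines fire at every position (co-located
    pairs); ``lag_pulses`` > 0 instead samples the second wavelength at
    the position ``lag_pulses`` later along the trajectory, to study
    interleaving misregistration.
    """
    hx, hy = phantom.extent
    out = (np.abs(traj.x) > hx + 1e-9) | (np.abs(traj.y) > hy + 1e-9)
    if out.any():
        k = int(np.nonzero(out)[0][0])
        raise ValueError(
            f"pulse {k} at ({traj.x[k]:.6g}, {traj.y[k]:.6g}) mm is outside the "
            f"phantom extent (+-{hx:.6g}, +-{hy:.6g}) mm"
        )
    rng = np.random.default_rng(seed)
    lams = [532, 558] if dual_wavelength else [int(wavelength)]
    ts, xs, ys, ws, amps = [], [], [], [], []
    for li, lam in enumerate(lams):
        if li > 0 and lag_pulses > 0:
            idx = np.minimum(np.arange(len(traj.x)) + lag_pulses, len(traj.x) - 1)
            px, py, pt = traj.x[idx], traj.y[idx], traj.t[idx]
        else:
            px, py, pt = traj.x, traj.y, traj.t
        a = _bilinear(phantom.mu_a[lam], px, py, phantom.pixel_size)
        if noise_sigma > 0:
            a = a + rng.normal(0.0, noise_sigma, size=a.shape)
        ts.append(pt)
        xs.append(px)
        ys.append(py)
        ws.append(np.full(len(px), lam, dtype=int))
        amps.append(np.clip(a, 0.0, None))
    return PulseRecordSet(
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        wavelength=np.concatenate(ws),
        amplitude=np.concatenate(amps),
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )


def reconstruct(
    prs: PulseRecordSet,
    grid_shape: int | tuple[int, int] = 512,
    pixel_size: float | None = None,
    method: str = "bin_mean",
    wavelength: int | None = None,
) -> ReconstructedImage:
    """Grid scattered pulse records onto pixels.

    ``bin_mean`` (the raw mode) averages all samples per pixel; pixels
    that received no pulse stay at zero with ``fill_mask`` false.
    ``nearest``/``linear`` evaluate a scattered interpolant at every pixel
    centre (``linear`` falls back to nearest outside the convex hull);
    the fill mask still marks genuinely sampled pixels.
    """
    if prs.n_records == 0:
        raise ValueError("empty record set")
    lams = prs.wavelengths()
    if wavelength is None:
        if len(lams) > 1:
            raise ValueError("record set holds several wavelengths; select one")
        wavelength = int(lams[0])
    else:
        prs = prs.select(int(wavelength))
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    if pixel_size is None:
        raise ValueError("pixel_size is required")
    ny, nx = grid_shape
    i, j = world_to_index(prs.x, prs.y, grid_shape, pixel_size)
    bad = (i < 0) | (i >= ny) | (j < 0) | (j >= nx)
    if bad.any():
        k = int(np.nonzero(bad)[0][0])
        raise ValueError(f"record {k} falls outside the reconstruction grid")
    counts = np.zeros(grid_shape, dtype=np.int64)
    sums = np.zeros(grid_shape, dtype=float)
    np.add.at(counts, (i, j), 1)
    np.add.at(sums, (i, j), prs.amplitude)
    fill = counts > 0
    pixels = np.zeros(grid_shape, dtype=float)
    pixels[fill] = sums[fill] / counts[fill]

    interpolated = False
    if method in ("nearest", "linear"):
        X, Y = pixel_center_coords(grid_shape, pixel_size)
        pts = np.column_stack([prs.x, prs.y])
        vals = interpolate.griddata(pts, prs.amplitude, (X, Y), method=method)
        if method == "linear":
            nn = interpolate.griddata(pts, prs.amplitude, (X, Y), method="nearest")
            vals = np.where(np.isnan(vals), nn, vals)
        pixels = vals
        interpolated = True
    elif method != "bin_mean":
        raise ValueError(f"unknown method {method!r}")

    return ReconstructedImage(
        pixels=pixels,
        fill_mask=fill,
        pixel_size=pixel_size,
        wavelength=int(wavelength),
        interpolated=interpolated,
        meta={"method": method, "n_records": prs.n_records},
    )


@dataclass
class RigidTransform2D:
    """Rotation + translation mapping moving coordinates into the fixed frame."""

    rotation: float  # rad
    translation: tuple[float, float]  # mm
    residual_rms: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform2D":
        Rt = self.matrix.T
        t = -Rt @ np.asarray(self.translation)
        return RigidTransform2D(rotation=-self.rotation, translation=(t[0], t[1]))

    def to_dict(self) -> dict:
        return {
            "rotation_rad": self.rotation,
            "translation_mm": list(self.translation),
            "residual_rms_mm": self.residual_rms,
        }


def fit_rigid(landmarks_moving, landmarks_fixed) -> RigidTransform2D:
    """Least-squares rigid transform (orthogonal Procrustes, no scaling).

    Finds the rotation R (det +1) and translation t minimising
    ``sum || R m_i + t - f_i ||^2`` over >= 2 non-coincident landmark
    pairs, and reports the residual RMS.
    """
    m = np.asarray(landmarks_moving, dtype=float)
    f = np.asarray(landmarks_fixed, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("landmark lists must be matching (N, 2) arrays")
    if len(m) < 2:
        raise ValueError("need at least 2 landmark pairs")
    mc = m - m.mean(axis=0)
    fc = f - f.mean(axis=0)
    if np.allclose(mc, 0) or np.allclose(fc, 0):
        raise ValueError("degenerate landmarks: all points coincident")
    H = mc.T @ fc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = f.mean(axis=0) - R @ m.mean(axis=0)
    angle = float(np.arctan2(R[1, 0], R[0, 0]))
    res = (m @ R.T + t) - f
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RigidTransform2D(rotation=angle, translation=(float(t[0]), float(t[1])), residual_rms=rms)


def stitch(
    images: list[ReconstructedImage],
    transforms: list[RigidTransform2D],
    blend: str = "feather_mean",
) -> ReconstructedImage:
    """Mosaic images into the union bounding box of their transformed extents.

    Each transform maps the image's own FOV-centred frame into the common
    frame.  ``feather_mean`` averages overlapping filled pixels with
    distance-to-edge weights (so seams fade); ``overwrite`` lets later
    images replace earlier ones.
    """
    if blend not in ("overwrite", "feather_mean"):
        raise ValueError("blend must be 'overwrite' or 'feather_mean'")
    if len(images) != len(transforms) or not images:
        raise ValueError("need one transform per image")
    d = images[0].pixel_size
    if any(abs(im.pixel_size - d) > 1e-12 for im in images):
        raise ValueError("all images must share a pixel size")

    # union bounding box of transformed corners, in the common frame
    corners = []
    for im, tr in zip(images, transforms):
        hx, hy = grid_half_extent(im.shape, d)
        c = np.array([[-hx, -hy], [-hx, hy], [hx, -hy], [hx, hy]])
        corners.append(tr.apply(c))
    allc = np.vstack(corners)
    xmin, ymin = allc.min(axis=0)
    xmax, ymax = allc.max(axis=0)
    nx = max(1, int(np.ceil((xmax - xmin) / d - 1e-9)))
    ny = max(1, int(np.ceil((ymax - ymin) / d - 1e-9)))
    cx, cy = (xmax + xmin) / 2.0, (ymax + ymin) / 2.0  # canvas centre, common frame

    Xc, Yc = pixel_center_coords((ny, nx), d)
    Xg, Yg = Xc + cx, Yc + cy

    acc = np.zeros((ny, nx))
    wacc = np.zeros((ny, nx))
    filled = np.zeros((ny, nx), dtype=bool)
    for im, tr in zip(images, transforms):
        inv = tr.inverse()
        pts = inv.apply(np.column_stack([Xg.ravel(), Yg.ravel()]))
        row, col = world_to_fractional_index(pts[:, 0], pts[:, 1], im.shape, d)
        eps = 1e-9
        inside = (
            (row > -0.5 - eps) & (row < im.shape[0] - 0.5 + eps)
            & (col > -0.5 - eps) & (col < im.shape[1] - 0.5 + eps)
        )
        vals = ndimage.map_coordinates(im.pixels, [row, col], order=1, mode="nearest")
        fm = ndimage.map_coordinates(
            im.fill_mask.astype(float), [row, col], order=0, mode="nearest"
        ) > 0.5
        fm &= inside
        if blend == "feather_mean":
            feather = ndimage.distance_transform_edt(im.fill_mask) + im.fill_mask
            w = ndimage.map_coordinates(feather, [row, col], order=1, mode="nearest")
            w = np.where(fm, np.maximum(w, 1e-6), 0.0)
            acc += (w * vals).reshape(ny, nx)
            wacc += w.reshape(ny, nx)
        else:
            sel = fm.reshape(ny, nx)
            acc[sel] = vals.reshape(ny, nx)[sel]
            wacc[sel] = 1.0
        filled |= fm.reshape(ny, nx)

    pixels = np.zeros((ny, nx))
    if blend == "feather_mean":
        nz = wacc > 0
        pixels[nz] = acc[nz] / wacc[nz]
    else:
        pixels = acc
    return ReconstructedImage(
        pixels=pixels,
        fill_mask=filled,
        pixel_size=d,
        wavelength=images[0].wavelength,
        interpolated=any(im.interpolated for im in images),
        meta={"blend": blend, "n_tiles": len(images), "canvas_center_mm": [cx, cy]},
    )
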