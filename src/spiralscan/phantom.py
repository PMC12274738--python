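"""Seeded synthetic vascular phantoms with exact ground truth.

A phantom is a planar scene of smooth vessel tubes on a dark background,
standing in for the mucosal microvasculature imaged by an endoscopic
scanner.  Every vessel carries a known centreline polyline (spline through
jittered control points), a diameter, an oxygen saturation and a relative
total-hemoglobin value, so the generating geometry doubles as the oracle
for the morphometry pipeline and the optical forward model

    mu_a(lambda) = eps_HbO2(lambda)*sO2*C_HbT + eps_Hb(lambda)*(1-sO2)*C_HbT

gives dual-wavelength absorption rasters consistent with the unmixing
module by construction.  Background pixels have C_HbT = 0 and hence zero
absorption.

Styles emulate the vascular scenes seen through an endoscope: ``parallel``
(dense longitudinally parallel vessels), ``grid`` (sparse reticular
pattern), ``loops`` (capillary hairpin loops) and ``random_tree``
(bifurcating arterial trees, the style with known branch points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import interpolate, ndimage

from .functional import ExtinctionTable, forward_amplitudes
from .morphometry import SkeletonNode, VesselGraph, VesselSegment

__all__ = ["VascularPhantom", "make_phantom", "PHANTOM_STYLES"]

PHANTOM_STYLES = ("parallel", "grid", "loops", "random_tree")

#: physiological sO2 defaults: arteries high, veins low
SO2_ARTERIAL = (0.95, 0.98)
SO2_VENOUS = (0.60, 0.75)


@dataclass
class VascularPhantom:
    """Ground-truth rasters plus the generating centreline graph."""

    truth_graph: VesselGraph
    so2_map: np.ndarray
    chbt_map: np.ndarray
    mu_a: dict  # wavelength (nm) -> raster
    vessel_mask: np.ndarray
    pixel_size: float
    rng_seed: int
    style: str
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.so2_map.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Half-width and half-height of the scene in mm."""
        ny, nx = self.shape
        return nx * self.pixel_size / 2.0, ny * self.pixel_size / 2.0

    def truth_report(self) -> dict:
        """Exact VL/NBP/MVD/VT from the generating geometry (mm units).

        MVD is length-weighted (matching the per-skeleton-point average of
        the estimator); VT is the unweighted per-segment mean.
        """
        g = self.truth_graph
        arcs = np.array([s.arc_length for s in g.segments])
        diam = np.array([float(np.mean(s.diameters)) for s in g.segments])
        ratios = [s.tortuosity for s in g.segments if s.chord_length > 0]
        return {
            "VL_mm": float(arcs.sum()),
            "NBP": g.n_branchpoints,
            "MVD_mm": float(np.average(diam, weights=arcs)),
            "VT": float(np.mean(ratios)) if ratios else float("nan"),
        }

    def save(self, outdir: str | Path) -> None:
        """Multi-page TIFF (mu_a 532, mu_a 558, sO2, C_HbT) + truth/provenance JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stack = np.stack(
            [self.mu_a[532], self.mu_a[558], self.so2_map, self.chbt_map]
        ).astype(np.float32)
        tifffile.imwrite(str(outdir / "phantom.tif"), stack, photometric="minisblack")
        truth = {
            "segments": [
                {
                    "arc_length_mm": s.arc_length,
                    "chord_length_mm": s.chord_length,
                    "mean_diameter_mm": float(np.mean(s.diameters)),
                    "points_px": s.points.tolist(),
                }
                for s in self.truth_graph.segments
            ],
            "n_branchpoints": self.truth_graph.n_branchpoints,
            "report": self.truth_report(),
        }
        (outdir / "truth_graph.json").write_text(json.dumps(truth, indent=2))
        (outdir / "provenance.json").write_text(
            json.dumps(
                {"style": self.style, "rng_seed": self.rng_seed,
                 "pixel_size_mm": self.pixel_size, **self.params},
                indent=2, sort_keys=True,
            )
        )


# ------------------------------------------------------------ centrelines
def _spline(ctrl: np.ndarray, n_dense: int = 400) -> np.ndarray:
    """Smooth (row, col) polyline through control points, densely sampled."""
    ctrl = np.asarray(ctrl, dtype=float)
    if len(ctrl) < 4:
        t = np.linspace(0, 1, n_dense)
        return (1 - t)[:, None] * ctrl[0] + t[:, None] * ctrl[-1]
    tck, _ = interpolate.splprep(ctrl.T, s=0, k=3)
    u = np.linspace(0, 1, n_dense)
    return np.array(interpolate.splev(u, tck)).T


def _jittered_line(rng, p0, p1, n_ctrl: int, jitter: float) -> np.ndarray:
    """Control points on the p0->p1 line with transverse jitter (ends pinned)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    t = np.linspace(0, 1, n_ctrl)
    base = (1 - t)[:, None] * p0 + t[:, None] * p1
    d = p1 - p0
    normal = np.array([-d[1], d[0]]) / max(np.hypot(*d), 1e-9)
    off = rng.normal(0.0, jitter, n_ctrl)
    off[0] = off[-1] = 0.0
    return base + off[:, None] * normal


@dataclass
class _Vessel:
    line: np.ndarray  # dense (row, col) polyline
    diameter_px: float
    so2: float
    chbt: float
    parent_node: int | None = None  # truth branchpoint id at the segment start


def _style_parallel(rng, size, density, drange) -> tuple[list[_Vessel], int]:
    m = 0.08 * size
    nv = max(2, round(8 * density))
    cols = np.linspace(m, size - m, nv)
    vessels = []
    for c in cols:
        ctrl = _jittered_line(rng, (m, c), (size - m, c), 6, 0.015 * size)
        vessels.append(_Vessel(_spline(ctrl), rng.uniform(*drange), 0.0, 0.0))
    return vessels, 0


def _style_grid(rng, size, density, drange) -> tuple[list[_Vessel], int]:
    m = 0.08 * size
    nv = max(2, round(3 * density))
    vessels = []
    for c in np.linspace(1.8 * m, size - 1.8 * m, nv):
        ctrl = _jittered_line(rng, (m, c), (size - m, c), 6, 0.01 * size)
        vessels.append(_Vessel(_spline(ctrl), rng.uniform(*drange), 0.0, 0.0))
    for r in np.linspace(1.8 * m, size - 1.8 * m, nv):
        ctrl = _jittered_line(rng, (r, m), (r, size - m), 6, 0.01 * size)
        vessels.append(_Vessel(_spline(ctrl), rng.uniform(*drange), 0.0, 0.0))
    return vessels, 0


def _style_loops(rng, size, density, drange) -> tuple[list[_Vessel], int]:
    m = 0.1 * size
    nv = max(1, round(4 * density))
    vessels = []
    for c in np.linspace(1.5 * m, size - 1.5 * m, nv):
        d = rng.uniform(*drange)
        gap = 3.0 * d
        top = m + rng.uniform(0, 0.1 * size)
        bot = size - m
        ctrl = np.array(
            [
                (bot, c - gap / 2),
                ((bot + top) / 2, c - gap / 2 + rng.normal(0, 0.01 * size)),
                (top + 0.04 * size, c - gap / 2),
                (top, c),
                (top + 0.04 * size, c + gap / 2),
                ((bot + top) / 2, c + gap / 2 + rng.normal(0, 0.01 * size)),
                (bot, c + gap / 2),
            ]
        )
        vessels.append(_Vessel(_spline(ctrl, 600), d, 0.0, 0.0))
    return vessels, 0


def _style_tree(rng, size, density, drange) -> tuple[list[_Vessel], int]:
    """Bifurcating trees; every internal node is a known branch point."""
    n_trees = max(1, round(density))
    d_hi = max(drange)
    vessels: list[_Vessel] = []
    nbp = 0
    depth_max = 3
    roots = np.linspace(0.3, 0.7, n_trees) * size if n_trees > 1 else np.array([0.5 * size])

    def grow(p0, angle, length, diam, depth, parent_node):
        nonlocal nbp
        p1 = p0 + length * np.array([-np.cos(angle), np.sin(angle)])
        p1 = np.clip(p1, 0.04 * size, 0.96 * size)
        ctrl = _jittered_line(rng, p0, p1, 5, 0.008 * size)
        vessels.append(_Vessel(_spline(ctrl, 300), diam, 0.0, 0.0, parent_node))
        if depth < depth_max:
            nbp += 1
            node_id = nbp
            spread = rng.uniform(0.5, 0.8)
            for sgn in (-1.0, 1.0):
                grow(
                    p1,
                    angle + sgn * spread + rng.normal(0, 0.05),
                    length * 0.66,
                    max(diam * 0.7, min(drange)),
                    depth + 1,
                    node_id,
                )

    for k, c in enumerate(roots):
        tilt = rng.normal(0, 0.1)
        grow(
            np.array([0.92 * size, c]),
            tilt,
            0.35 * size,
            d_hi,
            1,
            None,
        )
    return vessels, nbp


_STYLE_FN = {
    "parallel": _style_parallel,
    "grid": _style_grid,
    "loops": _style_loops,
    "random_tree": _style_tree,
}


# ------------------------------------------------------------- rasterising
def _rasterize(line: np.ndarray, diameter_px: float, shape) -> np.ndarray:
    """Tube mask: pixels within diameter/2 of the densely sampled centreline."""
    canvas = np.ones(shape, dtype=bool)
    ij = np.round(line).astype(int)
    ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1])]
    canvas[ij[:, 0], ij[:, 1]] = False
    dist = ndimage.distance_transform_edt(canvas)
    return dist <= diameter_px / 2.0


def _polyline_lengths(line: np.ndarray) -> tuple[float, float]:
    arc = float(np.sum(np.hypot(*np.diff(line, axis=0).T)))
    chord = float(np.hypot(*(line[-1] - line[0])))
    return arc, chord


def make_phantom(
    style: str = "random_tree",
    size: int = 512,
    seed: int = 0,
    vessel_density: float = 1.0,
    so2_range: tuple[float, float] | None = None,
    diameter_range: tuple[float, float] = (3.0, 8.0),
    chbt_range: tuple[float, float] = (0.9, 1.1),
    pixel_size: float | None = None,
    profile: str = "disk",
    ext: ExtinctionTable | None = None,
) -> VascularPhantom:
    """Generate a seeded phantom with known geometry and functional truth.

    Parameters
    ----------
    style:
        One of ``parallel``, ``grid``, ``loops``, ``random_tree``.
    size:
        Square raster side in pixels (>= 64).
    vessel_density:
        Scales the number of vessels; 1.0 is the nominal scene.
    so2_range:
        When given, every vessel draws its sO2 uniformly from this range;
        by default vessels alternate arterial (0.95-0.98) and venous
        (0.60-0.75).
    diameter_range:
        Vessel diameters in pixels.
    chbt_range:
        Relative total-hemoglobin per vessel (dimensionless; the system
        measures C_HbT only up to a scale).
    pixel_size:
        mm per pixel; default ``2.0 / size`` (a 2 mm FOV).
    profile:
        ``disk`` (uniform cross-section, default) or ``gaussian``
        (feathered edges on the absorption rasters).
    """
    if style not in PHANTOM_STYLES:
        raise ValueError(f"style must be one of {PHANTOM_STYLES}")
    if size < 64:
        raise ValueError("size must be >= 64 px")
    if pixel_size is None:
        pixel_size = 2.0 / size
    rng = np.random.default_rng(seed)
    vessels, nbp = _STYLE_FN[style](rng, size, vessel_density, diameter_range)

    shape = (size, size)
    so2_map = np.zeros(shape)
    chbt_map = np.zeros(shape)
    vessel_mask = np.zeros(shape, dtype=bool)
    segments: list[VesselSegment] = []
    nodes: list[SkeletonNode] = []

    for k, v in enumerate(vessels):
        if so2_range is not None:
            v.so2 = rng.uniform(*so2_range)
        else:
            lo, hi = SO2_ARTERIAL if k % 2 == 0 else SO2_VENOUS
            v.so2 = rng.uniform(lo, hi)
        v.chbt = rng.uniform(*chbt_range)
        tube = _rasterize(v.line, v.diameter_px, shape)
        vessel_mask |= tube
        so2_map[tube] = v.so2   # later vessels overwrite at overlaps
        chbt_map[tube] = v.chbt
        arc, chord = _polyline_lengths(v.line)
        segments.append(
            VesselSegment(
                points=v.line,
                arc_length=arc * pixel_size,
                chord_length=chord * pixel_size,
                diameters=np.full(len(v.line), v.diameter_px * pixel_size),
            )
        )

    coverage = vessel_mask.mean()
    if coverage > 0.9:
        raise ValueError(
            f"vessels cover {coverage:.0%} of the scene; too dense to "
            "skeletonize meaningfully — lower vessel_density"
        )

    # truth branch nodes (trees only); other styles have none by construction
    seen = set()
    for v in vessels:
        if v.parent_node is not None and v.parent_node not in seen:
            seen.add(v.parent_node)
            p = v.line[0]
            nodes.append(
                SkeletonNode(kind="branchpoint", pixels=np.array([np.round(p).astype(int)]),
                             centroid=(float(p[0]), float(p[1])))
            )

    mu532, mu558 = forward_amplitudes(so2_map, chbt_map, ext)
    if profile == "gaussian":
        sigma = 0.15 * float(np.mean([v.diameter_px for v in vessels]))
        mu532 = ndimage.gaussian_filter(mu532, sigma)
        mu558 = ndimage.gaussian_filter(mu558, sigma)
    elif profile != "disk":
        raise ValueError("profile must be 'disk' or 'gaussian'")

    return VascularPhantom(
        truth_graph=VesselGraph(nodes=nodes, segments=segments, pixel_size=pixel_size),
        so2_map=so2_map,
        chbt_map=chbt_map,
        mu_a={532: mu532, 558: mu558},
        vessel_mask=vessel_mask,
        pixel_size=pixel_size,
        rng_seed=seed,
        style=style,
        params={
            "size": size,
            "vessel_density": vessel_density,
            "diameter_range_px": list(diameter_range),
            "chbt_range": list(chbt_range),
            "so2_range": list(so2_range) if so2_range else None,
            "profile": profile,
            "n_vessels": len(vessels),
            "declared_nbp": nbp,
        },
    )
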