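"""Double-spiral resonant scanning trajectories.

A resonant MEMS scanner can sweep a circular field of view by rotating the
laser focus at constant angular velocity while the radial amplitude ramps
out and back — a *double spiral*: one outward pass from the centre to the
rim followed by one inward pass back to the centre, with no flyback.  Laser
pulses arrive at a fixed repetition rate, so samples are spaced at uniform
angular intervals.

Two radial laws are supported, plus their compound:

* Archimedes spiral (AS), ``r = a * theta``: uniform angular sampling puts
  the *point fraction* inside radius ``rho`` at ``rho / R`` — the centre is
  heavily oversampled relative to area.
* Fermat spiral (FS), ``r = a * sqrt(theta)``: point fraction inside
  ``rho`` is ``(rho / R) ** 2``, i.e. areally uniform density — the centre
  is sparse relative to AS, the rim dense.
* Compound A-FS: an AS pass and an FS pass joined at the rim into one
  continuous frame.  Its central point fraction is the mean of the two
  laws, roughly halving the central pulse load of AS while filling the rim
  like FS.

The return pass mirrors the radial law while the rotation keeps advancing
at the same rate, so the trajectory is continuous at every junction; the
return turns automatically fall at staggered angles relative to the
outward turns over most of the field.  An optional ``pass_phase_offset``
rotates the second pass rigidly for experimentation (it introduces a
junction step of ``R * offset`` and is off by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpiralParams",
    "ScanTrajectory",
    "DrivingWaveforms",
    "make_archimedes",
    "make_fermat",
    "make_compound",
    "make_trajectory",
    "driving_waveforms",
]

PATTERNS = ("AS", "FS", "AFS")
COMPOSITIONS = ("as_out_fs_in", "as_roundtrip_fs_roundtrip")

#: Maximum tolerated radial overshoot beyond the FOV radius (mm).
RADIUS_EPS = 1e-9


@dataclass(frozen=True)
class SpiralParams:
    """Parameters of one scan frame.

    Parameters
    ----------
    pattern:
        ``"AS"``, ``"FS"`` or ``"AFS"`` (compound Archimedes–Fermat).
    fov_diameter:
        Diameter of the circular field of view in mm.
    n_points:
        Laser pulses per frame.  Must be even (the frame splits into two
        equal passes); the compound round-trip composition needs a
        multiple of four.  Default 33332 pairs a 200 kHz pulse repetition
        rate with a 6 Hz frame rate.
    n_turns:
        Spiral revolutions per one-way pass.
    prf:
        Laser pulse repetition frequency in Hz.
    start_phase:
        Angular phase of the first sample (rad).
    composition:
        For ``AFS`` only: ``"as_out_fs_in"`` (default, one out-and-back
        frame) or ``"as_roundtrip_fs_roundtrip"`` (AS out+in then FS
        out+in, four passes).
    pass_phase_offset:
        Rigid angular offset of the second pass (rad).  Non-zero values
        break junction continuity by ``R * offset``; default 0.
    rng_seed:
        Unused by the deterministic generators; carried for provenance.
    """

    pattern: str
    fov_diameter: float = 2.0
    n_points: int = 33332
    n_turns: int = 16
    prf: float = 200_000.0
    start_phase: float = 0.0
    composition: str = "as_out_fs_in"
    pass_phase_offset: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.fov_diameter <= 0:
            raise ValueError("fov_diameter must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.n_points % 2:
            raise ValueError(
                "n_points must be even: a double-spiral frame splits its "
                "pulses equally between the outward and inward passes"
            )
        if self.pattern == "AFS" and self.composition not in COMPOSITIONS:
            raise ValueError(f"composition must be one of {COMPOSITIONS}")
        if (
            self.pattern == "AFS"
            and self.composition == "as_roundtrip_fs_roundtrip"
            and self.n_points % 4
        ):
            raise ValueError("four-pass compound frames need n_points divisible by 4")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        if self.prf <= 0:
            raise ValueError("prf must be positive")

    @property
    def radius(self) -> float:
        """FOV radius R in mm."""
        return self.fov_diameter / 2.0

    @property
    def frame_rate(self) -> float:
        """Frames per second; ``frame_rate * n_points == prf`` by construction."""
        return self.prf / self.n_points

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "fov_diameter": self.fov_diameter,
            "n_points": self.n_points,
            "n_turns": self.n_turns,
            "prf": self.prf,
            "start_phase": self.start_phase,
            "composition": self.composition,
            "pass_phase_offset": self.pass_phase_offset,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpiralParams":
        return cls(**d)


@dataclass
class ScanTrajectory:
    """Time-ordered planar sample positions of one scan frame.

    All arrays share length ``params.n_points``.  ``theta`` is the
    cumulative rotation angle (monotone increasing across the frame, rad);
    ``segment`` labels each sample with its pass
    (``AS_out``/``AS_in``/``FS_out``/``FS_in``).
    """

    params: SpiralParams
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    segment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = self.params.n_points
        for name in ("t", "x", "y", "r", "theta", "segment"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} must have length n_points={n}")
        if self.r.max() > self.params.radius + RADIUS_EPS:
            raise ValueError("trajectory exceeds the FOV radius")

    @property
    def n_points(self) -> int:
        return self.params.n_points

    def step_lengths(self) -> np.ndarray:
        """Euclidean distance between consecutive samples (mm)."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def segment_boundaries(self) -> np.ndarray:
        """Indices i where segment[i] != segment[i+1]."""
        return np.nonzero(self.segment[:-1] != self.segment[1:])[0]

    def junction_gaps(self) -> np.ndarray:
        """Euclidean gap across each segment junction (mm)."""
        steps = self.step_lengths()
        return steps[self.segment_boundaries()]

    def reversed(self) -> "ScanTrajectory":
        """Time-reversed copy (same timestamps, reversed visit order)."""
        return ScanTrajectory(
            params=self.params,
            t=self.t.copy(),
            x=self.x[::-1].copy(),
            y=self.y[::-1].copy(),
            r=self.r[::-1].copy(),
            theta=self.theta[::-1].copy(),
            segment=self.segment[::-1].copy(),
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write t_s,x_mm,y_mm,r_mm,theta_rad,segment CSV (+ JSON params sidecar)."""
        path = Path(path)
        pd.DataFrame(
            {
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "r_mm": self.r,
                "theta_rad": self.theta,
                "segment": self.segment,
            }
        ).to_csv(path, index=False)
        if sidecar:
            path.with_suffix(".json").write_text(
                json.dumps(self.params.to_dict(), indent=2, sort_keys=True)
            )

    @classmethod
    def from_csv(cls, path: str | Path, params: SpiralParams | None = None) -> "ScanTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        if params is None:
            params = SpiralParams.from_dict(json.loads(path.with_suffix(".json").read_text()))
        return cls(
            params=params,
            t=df["t_s"].to_numpy(),
            x=df["x_mm"].to_numpy(),
            y=df["y_mm"].to_numpy(),
            r=df["r_mm"].to_numpy(),
            theta=df["theta_rad"].to_numpy(),
            segment=df["segment"].to_numpy(dtype="U6"),
        )


def _radius_outward(kind: str, u: np.ndarray, radius: float) -> np.ndarray:
    """Radial law on the outward pass; u = theta / theta_max in [0, 1]."""
    if kind == "AS":
        return radius * u
    if kind == "FS":
        return radius * np.sqrt(u)
    raise ValueError(kind)


def _pass_u(n: int, outward: bool, include_apex: bool) -> np.ndarray:
    """Normalised angular progress of one pass.

    Outward passes run 0 -> 1 inclusive (the rim sample is exact); inward
    passes continue the rotation and descend 1 -> 0, starting one step in
    so the apex sample is not duplicated.
    """
    if outward:
        return np.linspace(0.0, 1.0, n) if include_apex else np.arange(n) / n
    return 1.0 - (np.arange(n) + 1.0) / n


def _assemble(params: SpiralParams, passes: list[tuple[str, str, bool]]) -> ScanTrajectory:
    """Build a trajectory from (radial_kind, label, outward) pass specs."""
    n = params.n_points
    npass = len(passes)
    per = n // npass
    theta_pass = 2.0 * np.pi * params.n_turns  # rotation per pass
    r_parts, th_parts, seg_parts = [], [], []
    theta0 = params.start_phase
    for k, (kind, label, outward) in enumerate(passes):
        u = _pass_u(per, outward, include_apex=True)
        r = _radius_outward(kind, u, params.radius)
        if outward:
            prog = np.linspace(0.0, 1.0, per) * theta_pass
        else:
            prog = (np.arange(per) + 1.0) / per * theta_pass
        th = theta0 + k * theta_pass + prog
        if k > 0:
            th = th + params.pass_phase_offset
        r_parts.append(r)
        th_parts.append(th)
        seg_parts.append(np.full(per, label, dtype="U6"))
    r = np.concatenate(r_parts)
    theta = np.concatenate(th_parts)
    segment = np.concatenate(seg_parts)
    t = np.arange(n) / params.prf
    return ScanTrajectory(
        params=params,
        t=t,
        x=r * np.cos(theta),
        y=r * np.sin(theta),
        r=r,
        theta=theta,
        segment=segment,
    )


def make_archimedes(params: SpiralParams) -> ScanTrajectory:
    """Archimedes double spiral: r = a*theta out to the rim and mirrored back.

    With uniform angular sampling the cumulative point fraction inside
    radius ``rho`` is ``rho / R``: dense centre, sparse rim.
    """
    if params.pattern != "AS":
        raise ValueError("make_archimedes requires pattern='AS'")
    return _assemble(params, [("AS", "AS_out", True), ("AS", "AS_in", False)])


def make_fermat(params: SpiralParams) -> ScanTrajectory:
    """Fermat double spiral: r = a*sqrt(theta), areally uniform sampling.

    Cumulative point fraction inside radius ``rho`` is ``(rho / R)**2``:
    sparse centre, dense rim.
    """
    if params.pattern != "FS":
        raise ValueError("make_fermat requires pattern='FS'")
    return _assemble(params, [("FS", "FS_out", True), ("FS", "FS_in", False)])


def make_compound(params: SpiralParams) -> ScanTrajectory:
    """Compound Archimedes–Fermat frame.

    Default composition: AS outward pass to the rim, then FS inward pass
    back to the centre, joined at r = R with matched position — one
    continuous resonant frame with no flyback.  Central point fractions
    are the mean of the AS and FS laws.
    """
    if params.pattern != "AFS":
        raise ValueError("make_compound requires pattern='AFS'")
    if params.composition == "as_out_fs_in":
        passes = [("AS", "AS_out", True), ("FS", "FS_in", False)]
    else:
        passes = [
            ("AS", "AS_out", True),
            ("AS", "AS_in", False),
            ("FS", "FS_out", True),
            ("FS", "FS_in", False),
        ]
    return _assemble(params, passes)


_MAKERS = {"AS": make_archimedes, "FS": make_fermat, "AFS": make_compound}


def make_trajectory(params: SpiralParams) -> ScanTrajectory:
    """Dispatch on ``params.pattern``."""
    return _MAKERS[params.pattern](params)


@dataclass
class DrivingWaveforms:
    """x/y position command series at the pulse rate, with junction report.

    ``junction_jump`` lists, for each segment junction, the first-difference
    discontinuity of the command series (mm); ``median_step`` is the median
    within-segment first difference, so smooth alignment means
    ``max(junction_jump) / median_step`` of order one.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    junction_index: np.ndarray
    junction_jump: np.ndarray
    median_step: float

    @property
    def max_junction_ratio(self) -> float:
        if len(self.junction_jump) == 0:
            return 0.0
        return float(self.junction_jump.max() / self.median_step)


def driving_waveforms(traj: ScanTrajectory) -> DrivingWaveforms:
    """Extract the scanner x(t), y(t) commands and verify smooth pass joins."""
    steps = traj.step_lengths()
    bounds = traj.segment_boundaries()
    within = np.ones(len(steps), dtype=bool)
    within[bounds] = False
    median_step = float(np.median(steps[within])) if within.any() else float("nan")
    return DrivingWaveforms(
        t=traj.t.copy(),
        x=traj.x.copy(),
        y=traj.y.copy(),
        junction_index=bounds,
        junction_jump=steps[bounds],
        median_step=median_step,
    )


def with_pattern(params: SpiralParams, pattern: str) -> SpiralParams:
    """Copy of ``params`` with a different pattern (convenience for comparisons)."""
    return replace(params, pattern=pattern)
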