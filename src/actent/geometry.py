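"""Filament geometry: traces, arc-length resampling, bending modes, curvature, energy.

A filament is an ordered list of 2D centerline points (micrometres).  Its
shape is decomposed into orthogonal bending modes of the tangent angle,

    theta(s) = sum_n a_n * sqrt(2/L) * cos(n*pi*s/L),        n = 1, 2, ...

the standard free-free cosine basis used in persistence-length analysis of
semi-flexible polymers.  The n = 0 term (rigid rotation) is excluded by
measuring theta relative to the shape's mean tangent angle, which makes the
amplitudes invariant under rigid-body motion.

Amplitudes are computed with midpoint quadrature on the segment-midpoint
tangent angles.  Because cos(n*pi*(j+1/2)/N) sampled at the N segment
midpoints is an exactly orthogonal family (the DCT-II nodes), decomposition
and synthesis (:func:`actent.synthetic.shape_from_modes`) round-trip to
machine precision on the retained mode subspace.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilamentShape",
    "FilamentTrajectory",
    "ModeTrajectory",
    "BendingEnergySeries",
    "MODE_BASIS_TAG",
    "resample_arclength",
    "tangent_angles",
    "decompose_modes",
    "modes_from_trajectory",
    "local_curvature",
    "taubin_circle_fit",
    "bending_energy",
    "bending_energy_series",
    "read_filament_traces",
    "write_filament_traces",
    "ACTIN_EI_PN_UM2",
]

#: Flexural rigidity of F-actin, pN*um^2 (literature value; configurable).
ACTIN_EI_PN_UM2 = 0.073

#: Basis convention tag recorded on every ModeTrajectory.
MODE_BASIS_TAG = "tangent-cosine-free-free"


@dataclass
class FilamentShape:
    """Ordered 2D centerline points with arc-length coordinates (um)."""

    points: np.ndarray  # (M, 2)
    s: np.ndarray = field(default=None)  # (M,) arc length per point

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (M, 2) array")
        if self.points.shape[0] < 4:
            raise ValueError("a filament shape needs at least 4 points")
        if self.s is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.s = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.s = np.asarray(self.s, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc length must be strictly increasing (repeated points?)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Contour length L in um."""
        return float(self.s[-1] - self.s[0])


@dataclass
class FilamentTrajectory:
    """Per-filament time series of centerline shapes."""

    filament_id: str
    frames: np.ndarray  # (T,) integer frame indices, strictly increasing
    shapes: list  # list of FilamentShape, one per frame
    frame_interval_s: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"filament {self.filament_id!r}: frame numbers must be strictly increasing"
            )
        if len(self.shapes) != len(self.frames):
            raise ValueError("frames and shapes length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval_s

    @property
    def usable_for_dynamics(self) -> bool:
        """Single-frame trajectories carry a shape but no dynamics."""
        return self.n_frames >= 2


@dataclass
class ModeTrajectory:
    """Bending-mode amplitude time series a(t): the phase-space trajectory.

    ``amplitudes`` is (T, n_modes); row t is the point a(t) in mode space.
    """

    amplitudes: np.ndarray
    times: np.ndarray
    lengths: np.ndarray  # filament contour length per frame (um)
    basis: str = MODE_BASIS_TAG

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.broadcast_to(
            np.asarray(self.lengths, dtype=float), (self.amplitudes.shape[0],)
        ).copy()
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("mode amplitudes must be finite")

    @property
    def n_modes(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def length(self) -> float:
        """Mean contour length over the trajectory."""
        return float(np.mean(self.lengths))


@dataclass
class BendingEnergySeries:
    """Per-frame bending energy E_bend and intensive energy per length."""

    times: np.ndarray
    energy: np.ndarray  # E_bend per frame (units of EI / um)
    energy_per_length: np.ndarray  # epsilon_bend = E_bend / L
    EI: float
    n_window: int


# ---------------------------------------------------------------------------
# resampling and tangent angles
# ---------------------------------------------------------------------------

def resample_arclength(shape: FilamentShape, n_points: int) -> FilamentShape:
    """Resample a shape to ``n_points`` equally spaced in arc length.

    Linear interpolation between existing points; the contour length is
    preserved to within the polyline discretisation (<0.1% for smooth traces).
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    s_new = np.linspace(shape.s[0], shape.s[-1], n_points)
    x = np.interp(s_new, shape.s, shape.points[:, 0])
    y = np.interp(s_new, shape.s, shape.points[:, 1])
    pts = np.column_stack([x, y])
    # keep the prescribed uniform arc-length coordinate rather than re-deriving
    # it from chords, so repeated resampling is stable
    return FilamentShape(pts, s=s_new - s_new[0])


def tangent_angles(shape: FilamentShape) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped tangent angle per segment and the segment-midpoint arc lengths.

    Returns ``(theta, s_mid)`` with one entry per segment (M-1 values).
    """
    d = np.diff(shape.points, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    s_mid = 0.5 * (shape.s[:-1] + shape.s[1:]) - shape.s[0]
    return theta, s_mid


def decompose_modes(shape: FilamentShape, n_modes: int) -> np.ndarray:
    """Bending-mode amplitudes a_1..a_n of a uniformly resampled shape.

    a_n = sqrt(2/L) * integral_0^L theta(s) cos(n*pi*s/L) ds, evaluated by
    midpoint quadrature on the segment tangent angles.  theta is measured
    relative to its mean, which removes the n = 0 rigid-rotation mode and
    makes the result rotation invariant.
    """
    seg = np.diff(shape.s)
    if not np.allclose(seg, seg[0], rtol=1e-6):
        raise ValueError("shape must be resampled to uniform arc-length spacing first")
    n_seg = shape.n_points - 1
    if n_modes > shape.n_points // 2:
        raise ValueError("n_modes must be <= n_points / 2")
    theta, s_mid = tangent_angles(shape)
    theta = theta - theta.mean()
    L = shape.length
    n = np.arange(1, n_modes + 1)
    basis = np.cos(np.pi * np.outer(n, s_mid) / L)  # (n_modes, n_seg)
    ds = L / n_seg
    return np.sqrt(2.0 / L) * ds * basis @ theta


def modes_from_trajectory(
    traj: FilamentTrajectory, n_modes: int = 2, n_points: int = 50
) -> ModeTrajectory:
    """Decompose every frame of a trajectory into bending-mode amplitudes."""
    amps = np.empty((traj.n_frames, n_modes))
    lengths = np.empty(traj.n_frames)
    for t, shp in enumerate(traj.shapes):
        rs = resample_arclength(shp, n_points)
        amps[t] = decompose_modes(rs, n_modes)
        lengths[t] = rs.length
    return ModeTrajectory(amps, traj.times, lengths)


# ---------------------------------------------------------------------------
# curvature and bending energy
# ---------------------------------------------------------------------------

def taubin_circle_fit(points: np.ndarray) -> float:
    """Curvature 1/R from Taubin's algebraic circle fit.

    Returns 0.0 for collinear points (infinite radius).  The Taubin fit is
    non-iterative and nearly unbiased for shallow arcs, which is exactly the
    regime of weakly bent semi-flexible filaments.
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    x = pts[:, 0] - c[0]
    y = pts[:, 1] - c[1]
    z = x * x + y * y
    zm = z.mean()
    if zm <= 0:
        return 0.0
    z0 = (z - zm) / (2.0 * np.sqrt(zm))
    A = np.column_stack([z0, x, y])
    # smallest singular vector of [z0 x y] gives the algebraic circle params
    _, sv, vt = np.linalg.svd(A, full_matrices=False)
    a0, a1, a2 = vt[-1]
    a0 /= 2.0 * np.sqrt(zm)
    b = -zm * a0
    # circle: a0*(x^2+y^2) + a1*x + a2*y + b = 0
    if abs(a0) < 1e-12:  # degenerate: a line
        return 0.0
    cx = -a1 / (2 * a0)
    cy = -a2 / (2 * a0)
    r2 = cx * cx + cy * cy - b / a0
    if r2 <= 0:
        return 0.0
    return 1.0 / np.sqrt(r2)


def local_curvature(shape: FilamentShape, n_window: int = 5) -> np.ndarray:
    """Local curvature kappa(s) from circles fit to rolling point windows.

    A circle is fit to each window of ``n_window`` consecutive points and
    1/R is assigned to the central point.  Points within n_window//2 points
    of either end have no centred window and carry NaN.
    """
    if n_window < 3 or n_window % 2 == 0:
        raise ValueError("n_window must be an odd integer >= 3")
    M = shape.n_points
    if n_window >= M:
        raise ValueError("n_window must be much smaller than the number of points")
    half = n_window // 2
    kappa = np.full(M, np.nan)
    for i in range(half, M - half):
        kappa[i] = taubin_circle_fit(shape.points[i - half : i + half + 1])
    return kappa


def bending_energy(
    shape: FilamentShape, EI: float = ACTIN_EI_PN_UM2, n_window: int = 5
) -> tuple[float, float]:
    """Bending energy E_bend = (EI/2) * integral kappa(s)^2 ds and E_bend/L.

    The integral runs over interior points only (endpoint exclusion from the
    rolling circle fit); the intensive value divides by the full contour
    length L.  With EI in pN*um^2 and lengths in um, E_bend is in pN*um.
    """
    kappa = local_curvature(shape, n_window)
    good = np.isfinite(kappa)
    E = 0.5 * EI * np.trapezoid(kappa[good] ** 2, shape.s[good])
    return float(E), float(E / shape.length)


def bending_energy_series(
    traj: FilamentTrajectory, EI: float = ACTIN_EI_PN_UM2, n_window: int = 5
) -> BendingEnergySeries:
    E = np.empty(traj.n_frames)
    eps = np.empty(traj.n_frames)
    for t, shp in enumerate(traj.shapes):
        E[t], eps[t] = bending_energy(shp, EI=EI, n_window=n_window)
    return BendingEnergySeries(traj.times, E, eps, EI, n_window)


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def _trajectories_from_table(
    df: pd.DataFrame, frame_interval_s: float
) -> list[FilamentTrajectory]:
    out = []
    for fid, g in df.groupby("filament_id", sort=True):
        frames = np.array(sorted(g["frame"].unique()), dtype=int)
        shapes = []
        for fr in frames:
            rows = g[g["frame"] == fr].sort_values("point_index")
            shapes.append(FilamentShape(rows[["x_um", "y_um"]].to_numpy()))
        out.append(
            FilamentTrajectory(str(fid), frames, shapes, frame_interval_s=frame_interval_s)
        )
    return out


def read_filament_traces(
    path,
    fmt: str = "csv",
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 1.0,
) -> list[FilamentTrajectory]:
    """Read tracked filament centerlines.

    Two formats are supported:

    ``csv``
        Columns ``filament_id, frame, point_index, x_um, y_um`` (already in
        micrometres; ``pixel_size_um`` is ignored).
    ``jfilament_snakes``
        Snake-tracker style text export: blocks introduced by a line
        ``# filament <id>``, followed by whitespace-separated rows
        ``frame point_index x_px y_px``.  Coordinates are in pixels and are
        multiplied by ``pixel_size_um``.

    Frames within a filament must be strictly increasing; a trajectory ends
    where tracking stops (e.g. a severing event).  Single-frame filaments are
    accepted but flagged (``usable_for_dynamics`` is False).
    """
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"filament_id", "frame", "point_index", "x_um", "y_um"} - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return _trajectories_from_table(df, frame_interval_s)
    if fmt == "jfilament_snakes":
        rows = []
        current = None
        text = path.read() if hasattr(path, "read") else open(path).read()
        for lineno, line in enumerate(io.StringIO(text), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2 and parts[0].lower() == "filament":
                    current = parts[1]
                continue
            if current is None:
                raise ValueError(f"line {lineno}: data row before any '# filament <id>' header")
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"line {lineno}: expected 'frame point_index x y', got {line!r}")
            try:
                fr, pi = int(parts[0]), int(parts[1])
                x, y = float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed number in {line!r}") from exc
            rows.append((current, fr, pi, x * pixel_size_um, y * pixel_size_um))
        df = pd.DataFrame(rows, columns=["filament_id", "frame", "point_index", "x_um", "y_um"])
        return _trajectories_from_table(df, frame_interval_s)
    raise ValueError(f"unknown trace format {fmt!r}")


def write_filament_traces(trajectories, path, fmt: str = "csv") -> None:
    """Write trajectories in either supported trace format (see reader)."""
    if fmt == "csv":
        rows = []
        for tr in trajectories:
            for fr, shp in zip(tr.frames, tr.shapes):
                for i, (x, y) in enumerate(shp.points):
                    rows.append((tr.filament_id, fr, i, x, y))
        pd.DataFrame(
            rows, columns=["filament_id", "frame", "point_index", "x_um", "y_um"]
        ).to_csv(path, index=False)
        return
    if fmt == "jfilament_snakes":
        lines = []
        for tr in trajectories:
            lines.append(f"# filament {tr.filament_id}")
            for fr, shp in zip(tr.frames, tr.shapes):
                for i, (x, y) in enumerate(shp.points):
                    lines.append(f"{fr} {i} {x:.6f} {y:.6f}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)
        return
    raise ValueError(f"unknown trace format {fmt!r}")
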