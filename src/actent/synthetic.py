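"""Synthetic data: every input the analysis chain consumes, with known ground truth.

The centrepiece is an overdamped Langevin process for the bending-mode
amplitudes,

    da = A a dt + sqrt(2 D) dW,

with drift matrix ``A`` (1/s) and diffusion matrix ``D`` (amplitude^2/s).
A symmetric drift with proportional diffusion satisfies detailed balance
(equilibrium, zero entropy production); an antisymmetric (nonreciprocal)
coupling between mode pairs breaks it.  For any stable linear process the
stationary covariance C solves the Lyapunov equation A C + C A^T + 2 D = 0,
the steady-state phase-space velocity field is v_ss(a) = (A + D C^-1) a, and
the mean entropy production rate has the closed form

    sigma = tr[(A + D C^-1)^T D^-1 (A + D C^-1) C],

which serves as the exact oracle for the trajectory-based estimator.

Image-side generators render filament stacks, striped director textures
(with optional +-1/2 disclination defects), myosin-like spot stacks with a
prescribed count schedule, and prescribed velocity fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter

from .geometry import FilamentShape, FilamentTrajectory, ModeTrajectory
from .kinematics import VelocityField

__all__ = [
    "LangevinSpec",
    "TextureSpec",
    "SpotStackSpec",
    "simulate_mode_dynamics",
    "simulate_activity_schedule",
    "ou_stationary_covariance",
    "ou_phase_velocity_matrix",
    "ou_entropy_rate",
    "nonreciprocal_drift",
    "shape_from_modes",
    "thermal_filament_shapes",
    "render_filament_stack",
    "render_texture",
    "render_spot_stack",
    "make_velocity_field",
    "advect_image",
]


# ---------------------------------------------------------------------------
# Langevin mode dynamics
# ---------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Parameters of the linear Langevin process for mode amplitudes.

    ``drift_matrix`` must be stable (all eigenvalues with negative real part)
    so that a stationary process exists; ``diffusion_matrix`` must be
    symmetric positive definite.
    """

    drift_matrix: np.ndarray
    diffusion_matrix: np.ndarray
    dt: float
    n_steps: int
    n_trajectories: int = 1
    seed: int = 0
    length_um: float = 10.0  # contour length attached to emitted trajectories

    def __post_init__(self):
        self.drift_matrix = np.atleast_2d(np.asarray(self.drift_matrix, dtype=float))
        self.diffusion_matrix = np.atleast_2d(np.asarray(self.diffusion_matrix, dtype=float))
        A, D = self.drift_matrix, self.diffusion_matrix
        if A.shape[0] != A.shape[1] or A.shape != D.shape:
            raise ValueError("drift and diffusion must be square matrices of equal size")
        if not np.allclose(D, D.T):
            raise ValueError("diffusion matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(D) <= 0):
            raise ValueError("diffusion matrix must be positive definite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ev = np.linalg.eigvals(A)
        if np.any(ev.real >= 0):
            raise ValueError(
                "drift matrix is not stable (eigenvalue with non-negative real part "
                f"{ev[np.argmax(ev.real)]:.4g}); no stationary process exists"
            )
        self._eigvals = ev

    @property
    def n_modes(self) -> int:
        return self.drift_matrix.shape[0]

    @property
    def slowest_relaxation_time(self) -> float:
        return 1.0 / np.min(-self._eigvals.real)


def ou_stationary_covariance(drift: np.ndarray, diffusion: np.ndarray) -> np.ndarray:
    """Stationary covariance C solving A C + C A^T + 2 D = 0."""
    return scipy.linalg.solve_continuous_lyapunov(
        np.asarray(drift, float), -2.0 * np.asarray(diffusion, float)
    )


def ou_phase_velocity_matrix(drift: np.ndarray, diffusion: np.ndarray) -> np.ndarray:
    """Matrix Omega with v_ss(a) = Omega a; Omega = A + D C^-1."""
    C = ou_stationary_covariance(drift, diffusion)
    return np.asarray(drift, float) + np.asarray(diffusion, float) @ np.linalg.inv(C)

def ou_entropy_rate(drift: np.ndarray, diffusion: np.ndarray) -> float:
    """Closed-form mean entropy production rate of the stationary process."""
    D = np.asarray(diffusion, float)
    C = ou_stationary_covariance(drift, D)
    Phi = np.asarray(drift, float) + D @ np.linalg.inv(C)
    return float(np.trace(Phi.T @ np.linalg.inv(D) @ Phi @ C))


def nonreciprocal_drift(k: float, alpha: float) -> np.ndarray:
    """Two-mode drift -k*I + alpha*J: relaxation plus nonreciprocal coupling.

    With unit diffusion the stationary covariance is I/k and the entropy
    production rate is 2*alpha^2/k.
    """
    return np.array([[-k, -alpha], [alpha, -k]])


def _em_run(A, B, dt, n_steps, state, rng):
    """Euler-Maruyama steps from ``state`` (n_traj, M); returns (n_steps, n_traj, M)."""
    out = np.empty((n_steps,) + state.shape)
    sqdt = np.sqrt(dt)
    for i in range(n_steps):
        noise = rng.standard_normal(state.shape)
        state = state + dt * state @ A.T + sqdt * noise @ B.T
        out[i] = state
    return out, state


def simulate_mode_dynamics(spec: LangevinSpec) -> list[ModeTrajectory]:
    """Euler-Maruyama trajectories of the mode-amplitude Langevin process.

    Initial conditions are drawn from the exact stationary distribution and a
    burn-in of 10 slowest relaxation times is discarded, so the recorded
    samples are stationary.  Fixed seed gives bit-identical output.  A dt
    larger than 0.1/|lambda_max| triggers a discretisation-bias warning.
    """
    A, D = spec.drift_matrix, spec.diffusion_matrix
    lam_max = np.max(np.abs(spec._eigvals))
    if lam_max * spec.dt > 0.1:
        warnings.warn(
            f"dt={spec.dt:g} is large for |lambda_max|={lam_max:g} "
            "(|lambda_max|*dt > 0.1): Euler-Maruyama bias may be significant",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    B = np.linalg.cholesky(2.0 * D)
    C = ou_stationary_covariance(A, D)
    Lc = np.linalg.cholesky(C)
    state = rng.standard_normal((spec.n_trajectories, spec.n_modes)) @ Lc.T
    n_burn = int(np.ceil(10.0 * spec.slowest_relaxation_time / spec.dt))
    _, state = _em_run(A, B, spec.dt, n_burn, state, rng)
    samples, _ = _em_run(A, B, spec.dt, spec.n_steps, state, rng)
    times = np.arange(spec.n_steps) * spec.dt
    return [
        ModeTrajectory(samples[:, j, :], times, np.full(spec.n_steps, spec.length_um))
        for j in range(spec.n_trajectories)
    ]


def simulate_activity_schedule(
    segments,
    dt: float,
    n_trajectories: int,
    seed: int = 0,
    length_um: float = 10.0,
) -> list[ModeTrajectory]:
    """Piecewise Langevin dynamics: a list of activity epochs run back to back.

    Each segment is a dict with keys ``n_steps``, ``drift`` and ``diffusion``;
    ``diffusion`` may be a single matrix or a pair ``(D_start, D_end)`` that
    is interpolated linearly across the segment (e.g. a rising effective
    temperature while motors accumulate).  The state is continuous across
    segment boundaries; the initial condition is stationary for segment 0.
    """
    rng = np.random.default_rng(seed)
    first = segments[0]
    A0 = np.atleast_2d(np.asarray(first["drift"], float))
    D0 = first["diffusion"]
    D0 = np.atleast_2d(np.asarray(D0[0] if isinstance(D0, (tuple, list)) else D0, float))
    C0 = ou_stationary_covariance(A0, D0)
    state = rng.standard_normal((n_trajectories, A0.shape[0])) @ np.linalg.cholesky(C0).T
    sqdt = np.sqrt(dt)
    chunks = []
    for seg in segments:
        A = np.atleast_2d(np.asarray(seg["drift"], float))
        Dspec = seg["diffusion"]
        if isinstance(Dspec, (tuple, list)):
            Da = np.atleast_2d(np.asarray(Dspec[0], float))
            Db = np.atleast_2d(np.asarray(Dspec[1], float))
        else:
            Da = Db = np.atleast_2d(np.asarray(Dspec, float))
        n = int(seg["n_steps"])
        out = np.empty((n, n_trajectories, A.shape[0]))
        for i in range(n):
            frac = i / max(n - 1, 1)
            D = (1 - frac) * Da + frac * Db
            B = np.linalg.cholesky(2.0 * D)
            noise = rng.standard_normal(state.shape)
            state = state + dt * state @ A.T + sqdt * noise @ B.T
            out[i] = state
        chunks.append(out)
    samples = np.concatenate(chunks, axis=0)
    times = np.arange(samples.shape[0]) * dt
    return [
        ModeTrajectory(samples[:, j, :], times, np.full(samples.shape[0], length_um))
        for j in range(n_trajectories)
    ]


# ---------------------------------------------------------------------------
# shape synthesis
# ---------------------------------------------------------------------------

def shape_from_modes(
    modes: np.ndarray,
    L: float = 10.0,
    n_points: int = 50,
    origin=(0.0, 0.0),
    mean_angle: float = 0.0,
) -> FilamentShape:
    """Build a 2D filament shape from bending-mode amplitudes.

    The tangent angle theta(s) = mean_angle + sum_n a_n sqrt(2/L)
    cos(n pi s / L) is evaluated at the segment midpoints and integrated to
    points at equal arc-length spacing, the exact inverse of
    :func:`actent.geometry.decompose_modes`.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    modes = np.atleast_1d(np.asarray(modes, dtype=float))
    n_seg = n_points - 1
    ds = L / n_seg
    s_mid = (np.arange(n_seg) + 0.5) * ds
    n = np.arange(1, modes.size + 1)
    theta = mean_angle + np.sqrt(2.0 / L) * (
        modes @ np.cos(np.pi * np.outer(n, s_mid) / L)
    )
    pts = np.empty((n_points, 2))
    pts[0] = origin
    pts[1:, 0] = origin[0] + np.cumsum(ds * np.cos(theta))
    pts[1:, 1] = origin[1] + np.cumsum(ds * np.sin(theta))
    return FilamentShape(pts, s=np.linspace(0.0, L, n_points))


def thermal_filament_shapes(
    persistence_length_um: float,
    L: float = 10.0,
    n_modes: int = 4,
    n_samples: int = 1000,
    n_points: int = 100,
    seed: int = 0,
) -> tuple[list[FilamentShape], np.ndarray]:
    """Equilibrium wormlike-chain shapes at persistence length l_p.

    Amplitudes are independent Gaussian draws from the Boltzmann weight of
    the bending Hamiltonian, <a_n^2> = 1 / (l_p (n pi / L)^2) — the
    stationary law of the thermal mode Langevin equation.  Returns the shapes
    and the drawn amplitudes (n_samples, n_modes).
    """
    rng = np.random.default_rng(seed)
    n = np.arange(1, n_modes + 1)
    std = 1.0 / (np.sqrt(persistence_length_um) * (n * np.pi / L))
    amps = rng.standard_normal((n_samples, n_modes)) * std
    shapes = [shape_from_modes(a, L=L, n_points=n_points) for a in amps]
    return shapes, amps


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _splat_points(image: np.ndarray, xs, ys, weights=None):
    """Bilinear accumulation of unit masses at subpixel (x, y) positions."""
    H, W = image.shape
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    w = np.ones_like(xs) if weights is None else np.asarray(weights, float)
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for dx, dy, ww in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + dx
        yi = y0 + dy
        ok = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        np.add.at(image, (yi[ok], xi[ok]), w[ok] * ww[ok])


def render_filament_stack(
    trajectories: list[FilamentTrajectory],
    image_shape=(256, 256),
    pixel_size_um: float = 0.2,
    psf_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval_s: float = 1.0,
):
    """Render tracked filaments into a fluorescence-like image stack.

    Each centerline is drawn as a Gaussian-profile line (amplitude ~1 at the
    ridge) plus additive Gaussian noise.  Returns ``(stack, metadata)`` where
    metadata carries pixel size and frame interval.  An empty trajectory list
    yields an empty stack with metadata.
    """
    meta = {
        "pixel_size_um": pixel_size_um,
        "frame_interval_s": frame_interval_s,
        "psf_sigma_px": psf_sigma_px,
        "noise_sd": noise_sd,
    }
    if not trajectories:
        return np.zeros((0,) + tuple(image_shape), dtype=float), meta
    all_frames = sorted({int(f) for tr in trajectories for f in tr.frames})
    rng = np.random.default_rng(seed)
    stack = np.zeros((len(all_frames),) + tuple(image_shape), dtype=float)
    step_px = 0.25  # dense sampling along the centerline, in pixels
    for ti, fr in enumerate(all_frames):
        img = stack[ti]
        for tr in trajectories:
            hits = np.nonzero(tr.frames == fr)[0]
            if hits.size == 0:
                continue
            shp = tr.shapes[hits[0]]
            s_dense = np.arange(0.0, shp.s[-1], step_px * pixel_size_um)
            xs = np.interp(s_dense, shp.s, shp.points[:, 0]) / pixel_size_um
            ys = np.interp(s_dense, shp.s, shp.points[:, 1]) / pixel_size_um
            _splat_points(img, xs, ys)
        img[:] = gaussian_filter(img, psf_sigma_px)
        peak = img.max()
        if peak > 0:
            img /= peak
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
    return stack, meta


@dataclass
class TextureSpec:
    """Striped texture with a prescribed director pattern.

    ``pattern`` is one of ``("uniform", angle_rad)``,
    ``("defect", charge, (cx_px, cy_px))`` with charge +-1/2, or
    ``("checkerboard", angle_a, angle_b)`` (quadrant blocks).
    """

    image_shape: tuple = (256, 256)
    pixel_size_um: float = 0.2
    pattern: tuple = ("uniform", 0.0)
    stripe_wavelength_um: float = 1.6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stripe_wavelength_um <= 2 * self.pixel_size_um:
            raise ValueError("stripe wavelength must exceed 2 pixels to be resolvable")
        if self.pattern[0] == "defect" and abs(self.pattern[1]) != 0.5:
            raise ValueError("defect charge must be +1/2 or -1/2")


def _director_truth(spec: TextureSpec) -> np.ndarray:
    H, W = spec.image_shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    kind = spec.pattern[0]
    if kind == "uniform":
        ang = np.full((H, W), float(spec.pattern[1]))
    elif kind == "checkerboard":
        a, b = float(spec.pattern[1]), float(spec.pattern[2])
        block = ((yy >= H / 2).astype(int) + (xx >= W / 2).astype(int)) % 2
        ang = np.where(block == 0, a, b)
    elif kind == "defect":
        charge = float(spec.pattern[1])
        cx, cy = spec.pattern[2]
        ang = charge * np.arctan2(yy - cy, xx - cx)
    else:
        raise ValueError(f"unknown pattern {kind!r}")
    return np.mod(ang, np.pi)


def render_texture(spec: TextureSpec):
    """Render a texture locally oriented along a prescribed director field.

    Uniform and checkerboard patterns are sine gratings with the wavevector
    perpendicular to the director.  For defect patterns no single-valued
    grating phase exists, so the texture is built from short Gaussian line
    segments oriented along the local ground-truth director.  Returns
    ``(image, truth_angles)`` with per-pixel angles folded to [0, pi).
    """
    H, W = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    truth = _director_truth(spec)
    lam_px = spec.stripe_wavelength_um / spec.pixel_size_um
    kind = spec.pattern[0]
    if kind in ("uniform", "checkerboard"):
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        # wavevector perpendicular to the (piecewise constant) director
        phase = (2 * np.pi / lam_px) * (-xx * np.sin(truth) + yy * np.cos(truth))
        img = 0.5 + 0.5 * np.cos(phase)
    else:
        img = np.zeros((H, W))
        seg_len = 2.0 * lam_px
        n_seg = int(4 * H * W / (seg_len * lam_px))
        cx = rng.uniform(0, W, n_seg)
        cy = rng.uniform(0, H, n_seg)
        ang = np.mod(
            float(spec.pattern[1]) * np.arctan2(cy - spec.pattern[2][1], cx - spec.pattern[2][0]),
            np.pi,
        )
        t = np.linspace(-0.5, 0.5, int(seg_len * 4))
        for x0, y0, a in zip(cx, cy, ang):
            _splat_points(img, x0 + seg_len * t * np.cos(a), y0 + seg_len * t * np.sin(a))
        img = gaussian_filter(img, lam_px / 8.0)
        if img.max() > 0:
            img /= img.max()
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img, truth


@dataclass
class SpotStackSpec:
    """Myosin-like diffraction-limited spot stack with a count schedule."""

    count_schedule: tuple
    spot_sigma_px: float = 2.0
    image_shape: tuple = (256, 256)
    field_area_um2: float = None
    pixel_size_um: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.count_schedule = tuple(int(c) for c in self.count_schedule)
        if any(c < 0 for c in self.count_schedule):
            raise ValueError("spot counts must be non-negative")
        if self.field_area_um2 is None:
            H, W = self.image_shape
            self.field_area_um2 = H * W * self.pixel_size_um**2


def render_spot_stack(spec: SpotStackSpec):
    """Render Gaussian spots with prescribed per-frame counts.

    Spots are placed uniformly at random with a minimum mutual separation of
    4 spot sigmas (rejection sampling) so that counting is unambiguous at
    zero noise.  Returns ``(stack, truth)`` where truth holds per-frame
    counts and spot positions (px).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    margin = 3 * spec.spot_sigma_px
    min_sep = 4 * spec.spot_sigma_px
    stack = np.zeros((len(spec.count_schedule), H, W))
    truth = {"counts": list(spec.count_schedule), "positions_px": []}
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    for ti, count in enumerate(spec.count_schedule):
        pts = []
        attempts = 0
        while len(pts) < count and attempts < 20000:
            cand = (rng.uniform(margin, W - margin), rng.uniform(margin, H - margin))
            if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep**2 for p in pts):
                pts.append(cand)
            attempts += 1
        if len(pts) < count:
            raise ValueError("could not place spots at the requested density")
        img = stack[ti]
        for x0, y0 in pts:
            img += np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * spec.spot_sigma_px**2))
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, img.shape)
        truth["positions_px"].append(pts)
    return stack, truth


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

def make_velocity_field(
    kind: tuple,
    extent_um: float = 50.0,
    n_grid: int = 26,
    frame_time_s: float = 0.0,
) -> VelocityField:
    """Prescribed velocity field on a uniform grid centred at the origin.

    ``kind`` is ``("uniform", (vx, vy))``, ``("radial", c)`` with
    v = -c r (divergence -2c in 2D), or ``("shear", gamma)`` with
    v = (gamma*y, 0) (divergence 0).
    """
    x = np.linspace(-extent_um / 2, extent_um / 2, n_grid)
    y = np.linspace(-extent_um / 2, extent_um / 2, n_grid)
    XX, YY = np.meshgrid(x, y)
    name = kind[0]
    if name == "uniform":
        vx = np.full_like(XX, float(kind[1][0]))
        vy = np.full_like(YY, float(kind[1][1]))
    elif name == "radial":
        c = float(kind[1])
        vx, vy = -c * XX, -c * YY
    elif name == "shear":
        g = float(kind[1])
        vx, vy = g * YY, np.zeros_like(XX)
    else:
        raise ValueError(f"unknown velocity field kind {name!r}")
    return VelocityField(x=x, y=y, vx=vx, vy=vy, time_s=frame_time_s)


def advect_image(
    image: np.ndarray, fld: VelocityField, dt: float, pixel_size_um: float
) -> np.ndarray:
    """Warp an image backward along a velocity field over time dt.

    Produces the second frame of a PIV pair whose true displacement is
    v*dt.  Interpolation is linear; the field is sampled at each pixel.
    """
    from scipy.ndimage import map_coordinates
    from scipy.interpolate import RegularGridInterpolator

    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    fx = RegularGridInterpolator((fld.y, fld.x), fld.vx, bounds_error=False, fill_value=0.0)
    fy = RegularGridInterpolator((fld.y, fld.x), fld.vy, bounds_error=False, fill_value=0.0)
    pts = np.column_stack([(yy * pixel_size_um).ravel(), (xx * pixel_size_um).ravel()])
    # grid coordinates are centred; shift pixel coordinates to the field frame
    pts[:, 0] += fld.y[0] if fld.y[0] < 0 else 0.0
    pts[:, 1] += fld.x[0] if fld.x[0] < 0 else 0.0
    dx = (fx(pts).reshape(H, W) * dt) / pixel_size_um
    dy = (fy(pts).reshape(H, W) * dt) / pixel_size_um
    return map_coordinates(image, [yy - dy, xx - dx], order=1, mode="nearest")
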