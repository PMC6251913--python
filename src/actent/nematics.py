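"""Nematic structure from fluorescence images: director field, order parameter q,
disclination defects, and myosin thick-filament density.

The local F-actin orientation is measured per window from the second-order
central moments of the window's Fourier power spectrum: an oriented texture
produces a power cloud elongated along its wavevector, so the director (the
stripe direction) is orthogonal to the axis of least second moment of the
spectrum.  Local order is then quantified with

    q = 2 < cos^2(theta) - 1/2 >,

where theta is the orientation difference between a window and each of its
8 neighbours in a 3x3 kernel: q = 1 for perfect co-alignment and q = 0 at
45 degree differences (the maximum expected in a quasi-2D network).
Angles are headless (folded to [0, pi)), measured counterclockwise from the
image x axis (columns), with pixel (0, 0) at top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import peak_local_max

__all__ = [
    "DirectorField",
    "DefectSet",
    "MyosinDensitySeries",
    "compute_director_field",
    "compute_order_parameter",
    "kernel_order",
    "mean_order",
    "order_change",
    "locate_defects",
    "count_intensity_peaks",
]


@dataclass
class DirectorField:
    """Grid of local orientations (rad, folded to [0, pi)) and order parameter q.

    ``angle`` and ``q`` are (ny, nx) arrays on window centers ``x``/``y``
    (um); NaN marks undefined entries (blank windows, borders for q).
    """

    x: np.ndarray
    y: np.ndarray
    angle: np.ndarray
    q: np.ndarray = None
    window_size_um: float = 3.5
    overlap: float = 0.5

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.angle = np.asarray(self.angle, float)
        if self.q is not None:
            self.q = np.asarray(self.q, float)

    @property
    def spacing_um(self) -> float:
        return float(np.mean(np.diff(self.x))) if self.x.size > 1 else self.window_size_um

    @property
    def e_par(self) -> np.ndarray:
        """(ny, nx, 2) unit vectors along the director."""
        return np.stack([np.cos(self.angle), np.sin(self.angle)], axis=-1)

    @property
    def e_perp(self) -> np.ndarray:
        """(ny, nx, 2) director rotated +90 degrees."""
        return np.stack([-np.sin(self.angle), np.cos(self.angle)], axis=-1)


@dataclass
class DefectSet:
    positions_um: np.ndarray  # (n, 2) as (x, y)
    charges: np.ndarray  # (n,) each +-1/2

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, float).reshape(-1, 2)
        self.charges = np.asarray(self.charges, float)
        if self.charges.size and not np.all(np.abs(self.charges) == 0.5):
            raise ValueError("defect charges must be +-1/2")

    def __len__(self):
        return self.charges.size


@dataclass
class MyosinDensitySeries:
    """Per-frame thick-filament counts and areal density (1/um^2)."""

    frames: np.ndarray
    times: np.ndarray
    counts: np.ndarray
    area_um2: float

    @property
    def density(self) -> np.ndarray:
        return self.counts / self.area_um2


# ---------------------------------------------------------------------------
# director field
# ---------------------------------------------------------------------------

def compute_director_field(
    image: np.ndarray,
    pixel_size_um: float,
    window_size_um: float = 3.5,
    overlap: float = 0.5,
    gaussian_sigma_px: float = None,
    dc_mask_px: float = 2.0,
) -> DirectorField:
    """Local orientation per overlapping window from FFT second moments.

    Each window is tapered by a Gaussian (default sigma = window/6 px, which
    suppresses edge leakage), Fourier transformed, and the orientation is
    taken orthogonal to the least-second-moment axis of the DC-masked power
    spectrum.  Windows with zero intensity variance are left undefined (NaN).
    """
    image = np.asarray(image, float)
    w = max(4, int(round(window_size_um / pixel_size_um)))
    step = max(1, int(round(w * (1.0 - overlap))))
    H, W = image.shape
    if H < w or W < w:
        raise ValueError("image smaller than a single window")
    if gaussian_sigma_px is None:
        gaussian_sigma_px = w / 6.0
    r0s = np.arange(0, H - w + 1, step)
    c0s = np.arange(0, W - w + 1, step)
    ang = np.full((r0s.size, c0s.size), np.nan)
    # Gaussian taper and frequency coordinates, shared by all windows
    idx = np.arange(w) - (w - 1) / 2.0
    taper = np.exp(-0.5 * (idx[:, None] ** 2 + idx[None, :] ** 2) / gaussian_sigma_px**2)
    fy = np.fft.fftshift(np.fft.fftfreq(w))[:, None] * w
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :] * w
    dc = (fx**2 + fy**2) <= dc_mask_px**2
    for i, r0 in enumerate(r0s):
        for j, c0 in enumerate(c0s):
            win = image[r0 : r0 + w, c0 : c0 + w]
            if win.std() == 0:
                continue
            win = (win - win.mean()) * taper
            P = np.abs(np.fft.fftshift(np.fft.fft2(win))) ** 2
            P[dc] = 0.0
            tot = P.sum()
            if tot <= 0:
                continue
            mu20 = (P * fx * fx).sum() / tot
            mu02 = (P * fy * fy).sum() / tot
            mu11 = (P * fx * fy).sum() / tot
            beta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)  # spectrum major axis
            ang[i, j] = np.mod(beta + np.pi / 2.0, np.pi)  # director _|_ to it
    x = (c0s + w / 2.0) * pixel_size_um
    y = (r0s + w / 2.0) * pixel_size_um
    return DirectorField(x=x, y=y, angle=ang, window_size_um=window_size_um, overlap=overlap)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def _fold_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Headless angle difference folded to [0, pi/2]."""
    d = np.mod(np.abs(a - b), np.pi)
    return np.minimum(d, np.pi - d)


def kernel_order(center: float, neighbors: np.ndarray) -> float:
    """q = 2<cos^2 dtheta - 1/2> of a center against its defined neighbours."""
    neighbors = np.asarray(neighbors, float)
    good = np.isfinite(neighbors)
    if not np.isfinite(center) or not good.any():
        return np.nan
    d = _fold_diff(center, neighbors[good])
    return float(2.0 * np.mean(np.cos(d) ** 2) - 1.0)


def compute_order_parameter(field: DirectorField) -> DirectorField:
    """Fill q for every interior window from its 3x3 neighbourhood.

    Undefined neighbours are excluded from the mean; a window whose kernel is
    entirely undefined carries no q.  Border windows carry no q.
    """
    a = field.angle
    ny, nx = a.shape
    if ny < 3 or nx < 3:
        raise ValueError("angle grid must be at least 3x3")
    q = np.full_like(a, np.nan)
    for i in range(1, ny - 1):
        for j in range(1, nx - 1):
            nb = np.concatenate(
                [a[i - 1, j - 1 : j + 2], [a[i, j - 1], a[i, j + 1]], a[i + 1, j - 1 : j + 2]]
            )
            q[i, j] = kernel_order(a[i, j], nb)
    return replace(field, q=q)


def mean_order(fields: list[DirectorField]) -> np.ndarray:
    """Spatial mean <q> per frame over defined windows."""
    out = np.empty(len(fields))
    for i, f in enumerate(fields):
        if f.q is None:
            raise ValueError("compute_order_parameter first")
        out[i] = np.nanmean(f.q) if np.isfinite(f.q).any() else np.nan
    return out


def order_change(q_means: np.ndarray, t_max: int = None) -> tuple[float, float]:
    """delta q = <q>(0) - <q>(t_max) and its fraction of <q>(0).

    ``t_max`` is the frame of extremal strain rate; defaults to the final
    frame.
    """
    q_means = np.asarray(q_means, float)
    if t_max is None:
        t_max = q_means.size - 1
    dq = float(q_means[0] - q_means[t_max])
    return dq, dq / float(q_means[0])


# ---------------------------------------------------------------------------
# defects
# ---------------------------------------------------------------------------

def _wrap_half(d: np.ndarray | float):
    """Wrap a director-angle difference into (-pi/2, pi/2]."""
    return -np.mod(-d + np.pi / 2.0, np.pi) + np.pi / 2.0


def locate_defects(field: DirectorField, merge_radius_windows: float = 1.0) -> DefectSet:
    """Half-integer disclinations from the winding of the director angle.

    The angle difference around each 2x2 plaquette (each step wrapped to
    (-pi/2, pi/2]) sums to +-pi at a +-1/2 defect and 0 elsewhere.
    Plaquettes touching undefined windows are skipped; detections within
    ``merge_radius_windows`` grid spacings are merged to their centroid.
    """
    a = field.angle
    ny, nx = a.shape
    raw = []
    for i in range(ny - 1):
        for j in range(nx - 1):
            loop = [a[i, j], a[i, j + 1], a[i + 1, j + 1], a[i + 1, j], a[i, j]]
            if not np.all(np.isfinite(loop)):
                continue
            wind = sum(_wrap_half(loop[k + 1] - loop[k]) for k in range(4))
            n_half = int(np.round(wind / np.pi))
            if n_half != 0:
                cx = 0.5 * (field.x[j] + field.x[j + 1])
                cy = 0.5 * (field.y[i] + field.y[i + 1])
                raw.append((cx, cy, 0.5 * np.sign(n_half)))
    if not raw:
        return DefectSet(np.empty((0, 2)), np.empty(0))
    merge_um = merge_radius_windows * field.spacing_um
    merged = []
    used = [False] * len(raw)
    for i, (x0, y0, s0) in enumerate(raw):
        if used[i]:
            continue
        cluster = [(x0, y0)]
        used[i] = True
        for j in range(i + 1, len(raw)):
            if used[j] or raw[j][2] != s0:
                continue
            if (raw[j][0] - x0) ** 2 + (raw[j][1] - y0) ** 2 <= merge_um**2:
                cluster.append(raw[j][:2])
                used[j] = True
        cx = np.mean([p[0] for p in cluster])
        cy = np.mean([p[1] for p in cluster])
        merged.append((cx, cy, s0))
    pos = np.array([(m[0], m[1]) for m in merged])
    charges = np.array([m[2] for m in merged])
    return DefectSet(pos, charges)


# ---------------------------------------------------------------------------
# myosin spot counting
# ---------------------------------------------------------------------------

def count_intensity_peaks(
    stack: np.ndarray,
    area_um2: float,
    min_distance_px: int = 5,
    threshold: float = 0.5,
    frame_interval_s: float = 1.0,
) -> MyosinDensitySeries:
    """Count fluorescence-intensity peaks per frame; density = count / area.

    Local maxima above ``threshold`` with non-maximum suppression at
    ``min_distance_px``.  A frame where more than 1% of pixels sit at the
    frame maximum is flagged as saturated with a warning; its count is still
    reported.
    """
    stack = np.atleast_3d(np.asarray(stack, float))
    if stack.ndim == 2:
        stack = stack[None]
    counts = np.empty(stack.shape[0], dtype=int)
    for t, frame in enumerate(stack):
        if frame.max() > threshold and np.mean(frame == frame.max()) > 0.01:
            warnings.warn(f"frame {t} looks saturated; peak count may be unreliable",
                          stacklevel=2)
        peaks = peak_local_max(
            frame, min_distance=min_distance_px, threshold_abs=threshold, exclude_border=False
        )
        counts[t] = peaks.shape[0]
    frames = np.arange(stack.shape[0])
    return MyosinDensitySeries(frames, frames * frame_interval_s, counts, area_um2)
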