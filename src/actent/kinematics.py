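"""Velocity fields, the macroscopic strain rate, and anisotropic flow correlations.

The strain rate psi(t) = <div v(t)> (spatial mean of the velocity-field
divergence) summarises network-scale motion: negative psi means contraction.
A network is classified contractile when the extremal |psi| exceeds
psi_c = 2e-3 1/s, stable below it, and thermal when no motors are present.

delta C_vv(r) = < C_perp(r,t)/C_perp(0,t) - C_par(r,t)/C_par(0,t) >_t
compares velocity coherence transverse vs parallel to the local filament
alignment; positive values flag transverse ("plucking") motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

__all__ = [
    "VelocityField",
    "StrainRateSeries",
    "AnisotropyCurve",
    "PSI_C_PER_S",
    "piv_velocity_field",
    "divergence",
    "mean_strain_rate",
    "anisotropic_velocity_autocorrelation",
]

#: Contractility threshold on |psi_max| (1/s).
PSI_C_PER_S = 2e-3


@dataclass
class VelocityField:
    """Velocity vectors on a uniform spatial grid (um, um/s)."""

    x: np.ndarray  # (nx,) grid coordinates
    y: np.ndarray  # (ny,)
    vx: np.ndarray  # (ny, nx)
    vy: np.ndarray  # (ny, nx)
    time_s: float = 0.0
    valid: np.ndarray = None  # (ny, nx) bool; None means all valid

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.vx = np.asarray(self.vx, float)
        self.vy = np.asarray(self.vy, float)
        if self.valid is None:
            self.valid = np.isfinite(self.vx) & np.isfinite(self.vy)
        else:
            self.valid = np.asarray(self.valid, bool)

    @property
    def spacing(self) -> tuple[float, float]:
        return float(np.mean(np.diff(self.x))), float(np.mean(np.diff(self.y)))


@dataclass
class StrainRateSeries:
    """psi(t) with its signed extremum and contractility classification."""

    times: np.ndarray
    psi: np.ndarray  # (T,) 1/s; NaN where undefined
    psi_c: float = PSI_C_PER_S
    no_myosin: bool = False
    psi_max: float = field(init=False)
    t_max: int = field(init=False)
    classification: str = field(init=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.psi = np.asarray(self.psi, float)
        finite = np.isfinite(self.psi)
        if not finite.any():
            raise ValueError("psi undefined at every frame")
        idx = np.nanargmax(np.abs(self.psi))
        self.t_max = int(idx)
        self.psi_max = float(self.psi[idx])  # signed value at extremal magnitude
        if self.no_myosin:
            self.classification = "thermal"
        elif abs(self.psi_max) > self.psi_c:
            self.classification = "contractile"
        else:
            self.classification = "stable"


@dataclass
class AnisotropyCurve:
    """delta C_vv(r): perpendicular-minus-parallel normalized autocorrelation."""

    r_um: np.ndarray
    dCvv: np.ndarray
    counts: np.ndarray  # frame-summed valid pair counts per bin


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _parabolic_refine(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Three-point parabolic sub-pixel refinement of a correlation peak."""
    i, j = peak
    di = dj = 0.0
    if 0 < i < corr.shape[0] - 1:
        c0, c1, c2 = corr[i - 1, j], corr[i, j], corr[i + 1, j]
        den = c0 - 2 * c1 + c2
        if den < 0:
            di = 0.5 * (c0 - c2) / den
    if 0 < j < corr.shape[1] - 1:
        c0, c1, c2 = corr[i, j - 1], corr[i, j], corr[i, j + 1]
        den = c0 - 2 * c1 + c2
        if den < 0:
            dj = 0.5 * (c0 - c2) / den
    return di, dj


def piv_velocity_field(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pixel_size_um: float,
    dt_s: float,
    interrogation_px: int = 32,
    search_px: int = 8,
    time_s: float = 0.0,
) -> VelocityField:
    """Single-pass cross-correlation PIV between two frames.

    Each non-overlapping interrogation window of ``frame_a`` is correlated
    against the corresponding region of ``frame_b`` extended by
    ``search_px`` on every side; the displacement is the correlation peak
    with parabolic sub-pixel refinement.  Windows without texture (flat
    correlation) are flagged invalid (NaN vectors).
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    H, W = frame_a.shape
    N, s = int(interrogation_px), int(search_px)
    rows = range(s, H - N - s + 1, N)
    cols = range(s, W - N - s + 1, N)
    ny, nx = len(list(rows)), len(list(cols))
    vx = np.full((ny, nx), np.nan)
    vy = np.full((ny, nx), np.nan)
    xs = np.empty(nx)
    ys = np.empty(ny)
    for ri, r0 in enumerate(range(s, H - N - s + 1, N)):
        ys[ri] = (r0 + N / 2) * pixel_size_um
        for ci, c0 in enumerate(range(s, W - N - s + 1, N)):
            xs[ci] = (c0 + N / 2) * pixel_size_um
            a = frame_a[r0 : r0 + N, c0 : c0 + N].astype(float)
            b = frame_b[r0 - s : r0 + N + s, c0 - s : c0 + N + s].astype(float)
            a = a - a.mean()
            b = b - b.mean()
            if a.std() == 0 or b.std() == 0:
                continue
            corr = fftconvolve(b, a[::-1, ::-1], mode="valid")  # (2s+1, 2s+1)
            if np.ptp(corr) == 0:
                continue
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            di, dj = _parabolic_refine(corr, pk)
            dy = pk[0] - s + di
            dx = pk[1] - s + dj
            vx[ri, ci] = dx * pixel_size_um / dt_s
            vy[ri, ci] = dy * pixel_size_um / dt_s
    return VelocityField(x=xs, y=ys, vx=vx, vy=vy, time_s=time_s)


# ---------------------------------------------------------------------------
# strain rate
# ---------------------------------------------------------------------------

def divergence(fld: VelocityField) -> np.ndarray:
    """Central-difference divergence per grid point (one-sided at borders)."""
    dx, dy = fld.spacing
    vx = np.where(fld.valid, fld.vx, np.nan)
    vy = np.where(fld.valid, fld.vy, np.nan)
    return np.gradient(vx, dx, axis=1) + np.gradient(vy, dy, axis=0)


def mean_strain_rate(
    fields: list[VelocityField],
    psi_c: float = PSI_C_PER_S,
    no_myosin: bool = False,
) -> StrainRateSeries:
    """psi(t) = <div v>: spatial mean of the divergence over valid points."""
    psi = np.empty(len(fields))
    times = np.empty(len(fields))
    for i, fld in enumerate(fields):
        if fld.valid.sum() < 4:
            psi[i] = np.nan
        else:
            div = divergence(fld)
            psi[i] = np.nanmean(div) if np.isfinite(div).any() else np.nan
        times[i] = fld.time_s
    return StrainRateSeries(times, psi, psi_c=psi_c, no_myosin=no_myosin)


# ---------------------------------------------------------------------------
# anisotropic velocity autocorrelation
# ---------------------------------------------------------------------------

def _nematic_angle_interpolator(director):
    """Interpolate a folded angle grid through its nematic tensor components."""
    c2 = np.cos(2 * director.angle)
    s2 = np.sin(2 * director.angle)
    ic = RegularGridInterpolator((director.y, director.x), c2, bounds_error=False)
    isn = RegularGridInterpolator((director.y, director.x), s2, bounds_error=False)

    def angle_at(pts_yx):
        return 0.5 * np.arctan2(isn(pts_yx), ic(pts_yx))

    return angle_at


def anisotropic_velocity_autocorrelation(
    fields: list[VelocityField],
    directors,
    r_bins_um: np.ndarray,
    min_pairs: int = 10,
) -> AnisotropyCurve:
    """delta C_vv(r) between velocity components along / across the director.

    At every valid grid point the velocity is projected onto the local
    parallel and perpendicular axes.  Each component is correlated along its
    own axis: the perpendicular component at separation r along e_perp, the
    parallel one along e_par.  Both correlations are normalized by their
    zero-lag value per frame, differenced and averaged over frames.
    ``directors`` is a single director field or one per frame.
    """
    r_bins_um = np.asarray(r_bins_um, float)
    per_frame = []
    counts = np.zeros(r_bins_um.size)
    if not isinstance(directors, (list, tuple)):
        directors = [directors] * len(fields)
    for fld, direc in zip(fields, directors):
        ang_at = _nematic_angle_interpolator(direc)
        XX, YY = np.meshgrid(fld.x, fld.y)
        pts = np.column_stack([YY.ravel(), XX.ravel()])
        phi = ang_at(pts).reshape(XX.shape)
        ok = fld.valid & np.isfinite(phi)
        if ok.sum() < min_pairs:
            continue
        cphi, sphi = np.cos(phi), np.sin(phi)
        v_par = fld.vx * cphi + fld.vy * sphi
        v_perp = -fld.vx * sphi + fld.vy * cphi
        ivx = RegularGridInterpolator((fld.y, fld.x), np.where(fld.valid, fld.vx, np.nan),
                                      bounds_error=False)
        ivy = RegularGridInterpolator((fld.y, fld.x), np.where(fld.valid, fld.vy, np.nan),
                                      bounds_error=False)
        c_perp0 = np.nanmean(np.where(ok, v_perp, np.nan) ** 2)
        c_par0 = np.nanmean(np.where(ok, v_par, np.nan) ** 2)
        if not (c_perp0 > 0 and c_par0 > 0):
            continue
        row = np.full(r_bins_um.size, np.nan)
        for bi, r in enumerate(r_bins_um):
            if r == 0:
                row[bi] = 0.0
                counts[bi] += ok.sum()
                continue
            # displaced sample points along each local axis
            xq_perp = XX - r * sphi
            yq_perp = YY + r * cphi
            xq_par = XX + r * cphi
            yq_par = YY + r * sphi
            p_perp = np.column_stack([yq_perp.ravel(), xq_perp.ravel()])
            p_par = np.column_stack([yq_par.ravel(), xq_par.ravel()])
            vxd = ivx(p_perp).reshape(XX.shape)
            vyd = ivy(p_perp).reshape(XX.shape)
            v_perp_d = -vxd * sphi + vyd * cphi
            vxd2 = ivx(p_par).reshape(XX.shape)
            vyd2 = ivy(p_par).reshape(XX.shape)
            v_par_d = vxd2 * cphi + vyd2 * sphi
            prod_perp = np.where(ok, v_perp * v_perp_d, np.nan)
            prod_par = np.where(ok, v_par * v_par_d, np.nan)
            n_perp = np.isfinite(prod_perp).sum()
            n_par = np.isfinite(prod_par).sum()
            if n_perp < min_pairs or n_par < min_pairs:
                continue
            row[bi] = np.nanmean(prod_perp) / c_perp0 - np.nanmean(prod_par) / c_par0
            counts[bi] += min(n_perp, n_par)
        per_frame.append(row)
    if not per_frame:
        raise ValueError("no frame produced a usable correlation")
    curve = np.nanmean(np.array(per_frame), axis=0)
    return AnisotropyCurve(r_bins_um, curve, counts)
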