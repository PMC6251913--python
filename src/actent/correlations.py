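"""Equal-time spatial fluctuation spectra transverse to the local alignment.

Density and director fluctuations are sampled along 1D profiles oriented
perpendicular to the local director (along e_perp) at every window center.
Per profile the mean is removed and the periodogram is computed,

    S(k) = |FFT(x - <x>)|^2 * dx / N,     k = 2*pi*f  (one-sided),

which by Wiener-Khinchin equals the Fourier transform of the equal-time
spatial autocorrelation.  Spectra are averaged over profiles (and frames)
and binned onto a perpendicular-wavenumber grid k_perp.  Director
fluctuations are scalarized as the signed small-angle deviation from the
profile's mean director, delta n_i = n_i - <n_i> to first order.

With this normalization zero-mean white noise of variance sigma^2 has a
flat spectrum at sigma^2*dx, and (1/pi) * sum S(k) dk recovers the profile
variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .nematics import DirectorField, _wrap_half

__all__ = [
    "CorrelationSpectrum",
    "sample_transverse_profiles",
    "director_fluctuation_profiles",
    "fluctuation_spectrum",
    "density_director_spectra",
]


@dataclass
class CorrelationSpectrum:
    """S_rho_rho and S_nn on a common k_perp grid (1/um)."""

    k_perp: np.ndarray
    S_rho_rho: np.ndarray
    S_nn: np.ndarray
    counts_rho: np.ndarray
    counts_nn: np.ndarray
    normalization: str = "periodogram*dx (one-sided, k=2*pi*f)"


def _profile_points(field: DirectorField, profile_length_um: float, spacing_um: float):
    """Sample positions (x, y) in um along e_perp for every defined window."""
    m = int(np.floor((profile_length_um / 2.0) / spacing_um))
    offsets = np.arange(-m, m + 1) * spacing_um
    pts = []
    for i in range(field.angle.shape[0]):
        for j in range(field.angle.shape[1]):
            a = field.angle[i, j]
            if not np.isfinite(a):
                continue
            ex, ey = -np.sin(a), np.cos(a)  # e_perp
            xs = field.x[j] + offsets * ex
            ys = field.y[i] + offsets * ey
            pts.append((xs, ys))
    return pts, offsets


def sample_transverse_profiles(
    values: np.ndarray,
    pixel_size_um: float,
    field: DirectorField,
    profile_length_um: float = 10.0,
    spacing_um: float = None,
):
    """1D profiles of a scalar image sampled along e_perp at window centers.

    Returns ``(profiles, truncated)``: profiles is (n, m) with NaN where a
    profile leaves the image, truncated flags those profiles.
    """
    if spacing_um is None:
        spacing_um = field.spacing_um
    pts, _ = _profile_points(field, profile_length_um, spacing_um)
    profiles = np.full((len(pts), 0 if not pts else len(pts[0][0])), np.nan)
    for n, (xs, ys) in enumerate(pts):
        profiles[n] = map_coordinates(
            np.asarray(values, float),
            [ys / pixel_size_um, xs / pixel_size_um],
            order=1,
            mode="constant",
            cval=np.nan,
        )
    truncated = ~np.isfinite(profiles).all(axis=1)
    return profiles, truncated


def director_fluctuation_profiles(
    field: DirectorField,
    profile_length_um: float = 10.0,
    spacing_um: float = None,
):
    """Signed director-deviation profiles delta n along e_perp.

    The folded angle grid is interpolated through its nematic tensor
    components; each profile's deviation is measured from its own mean
    director and wrapped to (-pi/2, pi/2].
    """
    if spacing_um is None:
        spacing_um = field.spacing_um
    pts, _ = _profile_points(field, profile_length_um, spacing_um)
    c2 = np.cos(2 * field.angle)
    s2 = np.sin(2 * field.angle)
    dx = field.spacing_um

    def samp(grid, xs, ys):
        return map_coordinates(
            grid,
            [(ys - field.y[0]) / dx, (xs - field.x[0]) / dx],
            order=1,
            mode="constant",
            cval=np.nan,
        )

    profiles = []
    truncated = []
    for xs, ys in pts:
        cc = samp(c2, xs, ys)
        ss = samp(s2, xs, ys)
        ang = 0.5 * np.arctan2(ss, cc)
        good = np.isfinite(cc) & np.isfinite(ss)
        if good.sum() < 2:
            continue
        mean_ang = 0.5 * np.arctan2(np.nanmean(ss[good]), np.nanmean(cc[good]))
        dev = _wrap_half(ang - mean_ang)
        dev[~good] = np.nan
        profiles.append(dev)
        truncated.append(not good.all())
    return np.array(profiles), np.array(truncated, bool)


def fluctuation_spectrum(
    profiles: np.ndarray,
    spacing_um: float,
    k_bins: np.ndarray = None,
    min_samples: int = 8,
):
    """Average periodogram of 1D profiles, binned onto a k_perp grid.

    Each profile is trimmed to its finite run, mean-subtracted, and its
    one-sided periodogram accumulated; profiles shorter than ``min_samples``
    are excluded (their number shows up in the returned counts).  Returns
    ``(k_perp, S, counts)`` with k_perp = 2*pi*f strictly positive.
    """
    profiles = np.atleast_2d(np.asarray(profiles, float))
    if profiles.shape[0] < 10:
        raise ValueError("need at least 10 profiles for a stable spectrum")
    pairs_k = []
    pairs_s = []
    for p in profiles:
        good = np.isfinite(p)
        if not good.any():
            continue
        idx = np.flatnonzero(good)
        p = p[idx[0] : idx[-1] + 1]
        if p.size < min_samples or not np.isfinite(p).all():
            continue
        x = p - p.mean()
        X = np.fft.rfft(x)
        N = x.size
        S = (np.abs(X) ** 2) * spacing_um / N
        f = np.fft.rfftfreq(N, d=spacing_um)
        pairs_k.append(2 * np.pi * f[1:])
        pairs_s.append(S[1:])
    if not pairs_k:
        raise ValueError("no profile long enough for a spectrum")
    k_all = np.concatenate(pairs_k)
    s_all = np.concatenate(pairs_s)
    if k_bins is None:
        # bin width = fundamental of the longest profile
        kmin = min(k[0] for k in pairs_k)
        kmax = k_all.max()
        k_bins = np.arange(kmin / 2, kmax + kmin, kmin)
    counts, _ = np.histogram(k_all, bins=k_bins)
    sums, _ = np.histogram(k_all, bins=k_bins, weights=s_all)
    centers = 0.5 * (k_bins[1:] + k_bins[:-1])
    keep = counts >= 1
    with np.errstate(invalid="ignore"):
        S_mean = sums[keep] / counts[keep]
    return centers[keep], S_mean, counts[keep]


def density_director_spectra(
    image: np.ndarray,
    pixel_size_um: float,
    field: DirectorField,
    profile_length_um: float = 10.0,
    spacing_um: float = None,
    k_bins: np.ndarray = None,
) -> CorrelationSpectrum:
    """S_rho_rho and S_nn from one image and its director field."""
    if spacing_um is None:
        spacing_um = field.spacing_um
    rho_profiles, _ = sample_transverse_profiles(
        image, pixel_size_um, field, profile_length_um, spacing_um
    )
    nn_profiles, _ = director_fluctuation_profiles(field, profile_length_um, spacing_um)
    k_rho, S_rho, n_rho = fluctuation_spectrum(rho_profiles, spacing_um, k_bins)
    if k_bins is None:
        # reuse the density grid so both spectra land on common bins
        dk = k_rho[1] - k_rho[0] if k_rho.size > 1 else k_rho[0]
        k_bins = np.concatenate([[k_rho[0] - dk / 2], k_rho + dk / 2])
    k_nn, S_nn, n_nn = fluctuation_spectrum(nn_profiles, spacing_um, k_bins)
    # align on the density grid; missing director bins become NaN
    S_nn_full = np.full_like(S_rho, np.nan)
    n_nn_full = np.zeros_like(n_rho)
    pos = {round(float(k), 9): i for i, k in enumerate(k_rho)}
    for k, s, n in zip(k_nn, S_nn, n_nn):
        i = pos.get(round(float(k), 9))
        if i is not None:
            S_nn_full[i] = s
            n_nn_full[i] = n
    return CorrelationSpectrum(k_rho, S_rho, S_nn_full, n_rho, n_nn_full)
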