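"""Entropy production from coarse-grained phase-space currents.

A filament's bending-mode amplitudes a(t) trace a trajectory in mode space.
Coarse-graining the instantaneous displacements onto a regular bin grid
gives the steady-state phase-space velocity v_ss; the total entropy
produced up to time t (natural units, k_B = T = 1) is the path integral

    Delta S(t) = int_0^t  a_dot(tau)^T  D^-1  v_ss[a(tau)]  d tau,

discretized as a Stratonovich sum: each step contributes
(Delta a)^T D^-1 v_ss evaluated in the bin containing the step midpoint.
D is the diffusion matrix of the underlying mode Langevin equation,
estimated from the transverse drag of a slender rod.  At equilibrium
(detailed balance) v_ss vanishes and Delta S has zero mean slope; broken
detailed balance produces a steadily growing Delta S whose rate is the
dissipation rate (energy = T * Delta S).

The detailed fluctuation theorem P(+dS)/P(-dS) = exp(dS) for windowed
entropy increments provides the internal consistency control: the slope of
ln[P(+)/P(-)] against dS must be 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ModeTrajectory

__all__ = [
    "PhaseSpaceField",
    "DiffusionModel",
    "EntropySeries",
    "phase_space_velocity_field",
    "entropy_production",
    "diffusion_matrix_slender_rod",
    "ensemble_dissipation_curve",
    "windowed_entropy_samples",
    "check_detailed_fluctuation_theorem",
    "WATER_VISCOSITY_PA_S",
    "ACTIN_DIAMETER_UM",
]

#: Solvent viscosity of water at room temperature (Pa s).
WATER_VISCOSITY_PA_S = 1e-3
#: F-actin diameter (um).
ACTIN_DIAMETER_UM = 7e-3


@dataclass
class PhaseSpaceField:
    """Binned steady-state velocity over mode space.

    ``edges`` holds the bin edges per dimension; ``velocity`` is
    (n_bins_1, ..., n_bins_M, M) with NaN where occupancy < min_count;
    ``counts`` the per-bin occupancy.
    """

    edges: list
    velocity: np.ndarray
    counts: np.ndarray
    min_count: int
    n_samples: int

    @property
    def n_modes(self) -> int:
        return len(self.edges)

    def bin_index(self, point: np.ndarray):
        """Multi-index of the bin containing ``point``, or None if outside."""
        idx = []
        for d, e in enumerate(self.edges):
            i = np.searchsorted(e, point[d], side="right") - 1
            if i < 0 or i >= e.size - 1:
                return None
            idx.append(i)
        return tuple(idx)

    def velocity_at(self, point: np.ndarray):
        """v_ss in the bin containing ``point``; None outside or under-occupied."""
        idx = self.bin_index(point)
        if idx is None:
            return None
        v = self.velocity[idx]
        return None if np.any(np.isnan(v)) else v


@dataclass
class DiffusionModel:
    """Mode-space diffusion matrix with its physical provenance."""

    D: np.ndarray
    viscosity_pa_s: float = WATER_VISCOSITY_PA_S
    length_um: float = 10.0
    diameter_um: float = ACTIN_DIAMETER_UM
    temperature: float = 1.0  # natural units k_B T

    def __post_init__(self):
        self.D = np.atleast_2d(np.asarray(self.D, float))
        if not np.allclose(self.D, self.D.T) or np.any(np.linalg.eigvalsh(self.D) <= 0):
            raise ValueError("diffusion matrix must be symmetric positive definite")

    @property
    def D_inv(self) -> np.ndarray:
        return np.linalg.inv(self.D)


@dataclass
class EntropySeries:
    """Cumulative entropy Delta S(t) for a single filament.

    ``entropy`` starts at 0; ``entropy_per_length`` is Delta s = Delta S / L.
    ``coverage`` is the fraction of steps whose midpoint fell in an occupied
    bin; results with coverage < 0.5 are flagged low-confidence.
    """

    times: np.ndarray
    entropy: np.ndarray
    entropy_per_length: np.ndarray
    coverage: float
    length_um: float
    low_confidence: bool = field(init=False)

    def __post_init__(self):
        self.low_confidence = self.coverage < 0.5

    @property
    def increments_per_length(self) -> np.ndarray:
        """Per-step Delta s increments (length T-1)."""
        return np.diff(self.entropy_per_length)


# ---------------------------------------------------------------------------
# coarse-grained phase-space velocity
# ---------------------------------------------------------------------------

def phase_space_velocity_field(
    trajectories: list[ModeTrajectory],
    bins_per_dim: int = 12,
    min_count: int = 10,
    span_sd: float = 4.0,
    edges: list = None,
) -> PhaseSpaceField:
    """Bin-averaged steady-state velocity over mode space.

    Every consecutive frame pair contributes one displacement velocity
    Delta a / Delta t assigned to the bin containing the pair midpoint
    (a(t) + a(t+dt))/2.  Bins seeing fewer than ``min_count`` transitions
    carry no velocity.  The default grid spans +-``span_sd`` sample standard
    deviations per dimension around the sample mean.
    """
    trajectories = [t for t in trajectories if t.n_frames >= 2]
    if not trajectories:
        raise ValueError("need at least one trajectory with >= 2 frames")
    basis = {t.basis for t in trajectories}
    if len(basis) > 1:
        raise ValueError(f"trajectories mix mode bases: {sorted(basis)}")
    M = trajectories[0].n_modes
    all_pts = np.concatenate([t.amplitudes for t in trajectories])
    if edges is None:
        mu = all_pts.mean(axis=0)
        sd = all_pts.std(axis=0)
        sd[sd == 0] = 1.0
        edges = [
            np.linspace(mu[d] - span_sd * sd[d], mu[d] + span_sd * sd[d], bins_per_dim + 1)
            for d in range(M)
        ]
    shape = tuple(e.size - 1 for e in edges)
    vel_sum = np.zeros(shape + (M,))
    counts = np.zeros(shape, dtype=int)
    n_samples = 0
    for tr in trajectories:
        a = tr.amplitudes
        dt = np.diff(tr.times)
        mids = 0.5 * (a[:-1] + a[1:])
        vels = np.diff(a, axis=0) / dt[:, None]
        idx_per_dim = []
        inside = np.ones(mids.shape[0], dtype=bool)
        for d in range(M):
            i = np.searchsorted(edges[d], mids[:, d], side="right") - 1
            inside &= (i >= 0) & (i < shape[d])
            idx_per_dim.append(np.clip(i, 0, shape[d] - 1))
        flat = np.ravel_multi_index([i[inside] for i in idx_per_dim], shape)
        np.add.at(counts.reshape(-1), flat, 1)
        for d in range(M):
            np.add.at(vel_sum.reshape(-1, M)[:, d], flat, vels[inside, d])
        n_samples += int(inside.sum())
    if n_samples == 0 or counts.max() < min_count:
        raise ValueError(
            "all phase-space bins are under-occupied; use coarser bins or more data"
        )
    velocity = np.full(shape + (M,), np.nan)
    occ = counts >= min_count
    velocity[occ] = vel_sum[occ] / counts[occ][..., None]
    return PhaseSpaceField(list(edges), velocity, counts, min_count, n_samples)


# ---------------------------------------------------------------------------
# the entropy integral
# ---------------------------------------------------------------------------

def entropy_production(
    traj: ModeTrajectory,
    fld: PhaseSpaceField,
    diffusion: DiffusionModel,
    exclude_self: bool = True,
) -> EntropySeries:
    """Cumulative Delta S(t) for one filament (Eq. of the module docstring).

    Stratonovich discretization: per step, (Delta a)^T D^-1 v_ss[midpoint].
    Steps whose midpoint lands in an unoccupied or out-of-grid bin contribute
    zero and lower the coverage diagnostic (bias is toward underestimation).

    With ``exclude_self`` (default) v_ss is evaluated leave-one-trajectory-
    out: this trajectory's own displacements are subtracted from every bin
    mean, so each step is integrated against a field built only from the
    other trajectories.  Statistical coupling between a trajectory and its
    own contribution to the coarse-grained field otherwise accumulates into
    a spurious entropy rate at equilibrium (positive from the step's own
    term, negative from temporally correlated same-bin steps).  Set it to
    False when the trajectory did not contribute to ``fld`` or when the
    field comes from a single (e.g. deterministic) trajectory.
    """
    if fld.n_modes != traj.n_modes or diffusion.D.shape[0] != traj.n_modes:
        raise ValueError("trajectory, field and diffusion must share the mode dimension")
    a = traj.amplitudes
    mids = 0.5 * (a[:-1] + a[1:])
    da = np.diff(a, axis=0)
    Dinv = diffusion.D_inv
    shape = tuple(e.size - 1 for e in fld.edges)
    inside = np.ones(mids.shape[0], dtype=bool)
    idx_per_dim = []
    for d in range(fld.n_modes):
        i = np.searchsorted(fld.edges[d], mids[:, d], side="right") - 1
        inside &= (i >= 0) & (i < shape[d])
        idx_per_dim.append(np.clip(i, 0, shape[d] - 1))
    flat = np.ravel_multi_index(idx_per_dim, shape)
    v = fld.velocity.reshape(-1, fld.n_modes)[flat]
    ok = inside & np.all(np.isfinite(v), axis=1)
    if exclude_self:
        n_bins_flat = int(np.prod(shape))
        counts = fld.counts.reshape(-1)[flat].astype(float)
        dt = np.diff(traj.times)[:, None]
        own = da / dt
        own_n = np.bincount(flat[inside], minlength=n_bins_flat).astype(float)
        own_sum = np.column_stack(
            [
                np.bincount(flat[inside], weights=own[inside, d], minlength=n_bins_flat)
                for d in range(fld.n_modes)
            ]
        )
        remain = counts - own_n[flat]
        with np.errstate(invalid="ignore", divide="ignore"):
            v_loo = (counts[:, None] * v - own_sum[flat]) / remain[:, None]
        v = np.where(remain[:, None] > 0, v_loo, np.nan)
        ok &= remain > 0
    inc = np.zeros(da.shape[0])
    inc[ok] = np.einsum("ij,jk,ik->i", da[ok], Dinv, v[ok])
    coverage = ok.sum() / max(da.shape[0], 1)
    dS = np.concatenate([[0.0], np.cumsum(inc)])
    L = traj.length
    return EntropySeries(traj.times, dS, dS / L, coverage, L)


def diffusion_matrix_slender_rod(
    L_um: float,
    diameter_um: float = ACTIN_DIAMETER_UM,
    viscosity_pa_s: float = WATER_VISCOSITY_PA_S,
    temperature: float = 1.0,
    n_modes: int = 2,
) -> DiffusionModel:
    """Diffusion matrix from the transverse drag of a slender rod.

    Per-unit-length perpendicular drag zeta = 4*pi*eta / (ln(L/d) + 0.84);
    in the orthonormal mode basis every mode feels the drag gamma = zeta*L,
    so D = (T / gamma) * I.  With eta in Pa s = pN s/um^2 and L in um,
    gamma is in pN s and D in (k_B T units) um / (pN s).
    """
    if not (L_um > diameter_um > 0):
        raise ValueError("need L > d > 0")
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    zeta_perp = 4 * np.pi * viscosity_pa_s / (np.log(L_um / diameter_um) + 0.84)
    gamma = zeta_perp * L_um
    D = (temperature / gamma) * np.eye(n_modes)
    return DiffusionModel(D, viscosity_pa_s, L_um, diameter_um, temperature)


def ensemble_dissipation_curve(
    series: list[EntropySeries], temperature: float = 1.0
):
    """Ensemble-mean dissipated energy per unit length over time.

    At each frame the mean per-length entropy increment is taken over the
    filaments present at that frame; the cumulative sum of the means, times
    T, is the dissipation curve (a filament appearing mid-experiment simply
    joins the average from its first frame on).  Returns ``(times, curve)``.
    """
    if not series:
        raise ValueError("empty ensemble")
    all_times = np.unique(np.concatenate([s.times for s in series]))
    inc_sum = np.zeros(all_times.size - 1 if all_times.size > 1 else 0)
    inc_n = np.zeros_like(inc_sum)
    for s in series:
        incs = s.increments_per_length
        # map this filament's step intervals onto the global frame axis
        starts = np.searchsorted(all_times, s.times[:-1])
        np.add.at(inc_sum, starts, incs)
        np.add.at(inc_n, starts, 1.0)
    mean_inc = np.where(inc_n > 0, inc_sum / np.maximum(inc_n, 1), 0.0)
    curve = temperature * np.concatenate([[0.0], np.cumsum(mean_inc)])
    return all_times, curve


# ---------------------------------------------------------------------------
# detailed fluctuation theorem control
# ---------------------------------------------------------------------------

def windowed_entropy_samples(series: list[EntropySeries], window: int) -> np.ndarray:
    """Entropy produced over non-overlapping windows of ``window`` steps."""
    out = []
    for s in series:
        dS = s.entropy
        n = (dS.size - 1) // window
        for i in range(n):
            out.append(dS[(i + 1) * window] - dS[i * window])
    return np.asarray(out)


def check_detailed_fluctuation_theorem(
    samples: np.ndarray, n_bins: int = 20
):
    """Slope and 95% CI of ln[P(+dS)/P(-dS)] versus dS.

    The histogram uses bins placed symmetrically about 0; each bin pair with
    counts on both sides contributes y = ln(N+/N-) at the bin-center dS with
    weight from the counting error var(y) = 1/N+ + 1/N-.  A weighted linear
    fit through the origin returns the slope; slope = 1 indicates compliance
    with the detailed fluctuation theorem.
    """
    samples = np.asarray(samples, float)
    if samples.size < 500:
        raise ValueError("need at least 500 window samples for a stable histogram")
    lim = np.max(np.abs(samples))
    edges = np.linspace(-lim, lim, 2 * n_bins + 1)  # symmetric about 0
    counts, _ = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xs, ys, ws = [], [], []
    for i in range(n_bins):
        ip = n_bins + i  # bin with center +c
        im = n_bins - 1 - i  # mirror bin with center -c
        np_, nm = counts[ip], counts[im]
        if np_ > 0 and nm > 0:
            xs.append(centers[ip])
            ys.append(np.log(np_ / nm))
            ws.append(1.0 / (1.0 / np_ + 1.0 / nm))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable symmetric bin pairs; collect more samples")
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = np.asarray(ws)
    slope = np.sum(w * x * y) / np.sum(w * x * x)
    se = 1.0 / np.sqrt(np.sum(w * x * x))
    return slope, (slope - 1.96 * se, slope + 1.96 * se)
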