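"""End-to-end orchestration: state segmentation, state-wise slopes, and the
full synthetic or trace-driven analysis run.

An experiment passes through three states read off the myosin thick-filament
density time series: S0 (before thick filaments form), S1 (thick filaments
accumulating, non-contractile) and C (contractile; tracked thick-filament
counts fall as motors aggregate, so C starts at the density peak).  Slopes
of the dissipation and bending-energy curves are fit per state by ordinary
least squares and normalized to the S1 slope of the same experiment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import entropy as ent
from . import geometry as geo
from . import kinematics as kin
from . import nematics as nem
from . import synthetic as syn
from .correlations import density_director_spectra
from .nematics import MyosinDensitySeries

__all__ = [
    "StateSegmentation",
    "StateSlopes",
    "segment_states",
    "state_slopes",
    "dissipation_vs_density",
    "default_synthetic_config",
    "run_pipeline",
]


@dataclass
class StateSegmentation:
    """Frame ranges of the S0 / S1 / C states of one experiment.

    Boundaries are carried both as frame indices into the density series and
    as absolute times, so curves sampled on other time grids can be
    partitioned consistently (one segmentation per experiment serves both
    the dissipation and bending analyses).
    """

    times: np.ndarray  # density-series times
    density: np.ndarray
    onset_frame: int  # first frame of S1
    peak_frame: int  # first frame of C (density maximum)
    has_contractile: bool
    rho_c: float  # density at the peak
    onset_threshold: float

    @property
    def onset_time(self) -> float:
        return float(self.times[self.onset_frame]) if self.onset_frame < self.times.size \
            else float(self.times[-1]) + 1.0

    @property
    def peak_time(self) -> float:
        if not self.has_contractile:
            return float(self.times[-1]) + 1.0
        return float(self.times[self.peak_frame])

    def state_of_times(self, times: np.ndarray) -> np.ndarray:
        """Label an arbitrary time axis with 'S0' / 'S1' / 'C'."""
        times = np.asarray(times, float)
        out = np.full(times.shape, "S0", dtype=object)
        out[times >= self.onset_time] = "S1"
        if self.has_contractile:
            out[times >= self.peak_time] = "C"
        return out


@dataclass
class StateSlopes:
    """Per-state OLS slopes, raw and normalized to S1."""

    raw: dict  # state -> slope (per unit time); NaN if state unusable
    stderr: dict
    normalized: dict  # raw / raw['S1']; NaN if S1 slope is 0 or missing
    quantity: str = "dissipation"


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return np.asarray(x, float)
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(np.asarray(x, float), pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")
    return sm[pad : pad + len(x)]


def segment_states(
    density: MyosinDensitySeries,
    onset_threshold: float = None,
    smooth_window: int = 5,
) -> StateSegmentation:
    """Split an experiment into S0 / S1 / C from the myosin density series.

    The series is smoothed by a moving average; S0 ends at the first
    *sustained* exceedance of ``onset_threshold`` (default 5% of the series
    maximum) — the smoothed density must stay above threshold for three
    consecutive frames, which suppresses spurious onsets from baseline noise
    — and C starts at the smoothed-density maximum.  A series that is still
    rising at the last frame has no contractile state (C empty, flagged); an
    all-zero series is entirely S0.
    """
    rho = density.density
    if rho.size < 3:
        raise ValueError("need at least 3 frames to segment states")
    sm = _moving_average(rho, smooth_window)
    if sm.max() <= 0:
        return StateSegmentation(
            density.times, rho, rho.size, rho.size, False, 0.0, 0.0
        )
    if onset_threshold is None:
        onset_threshold = 0.05 * sm.max()
    above = sm > onset_threshold
    run = 3
    sustained = np.flatnonzero(
        np.convolve(above.astype(int), np.ones(run), mode="valid") == run
    )
    onset = int(sustained[0]) if sustained.size else rho.size
    peak = int(np.argmax(sm))
    has_c = peak < rho.size - 1
    if not has_c:
        peak = rho.size
    peak = max(peak, onset)
    return StateSegmentation(
        density.times, rho, onset, min(peak, rho.size - 1) if has_c else rho.size,
        has_c, float(rho[min(peak, rho.size - 1)] if rho.size else 0.0), onset_threshold
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm = t - t.mean()
    sxx = np.sum(tm**2)
    slope = np.sum(tm * y) / sxx
    resid = y - y.mean() - slope * tm
    dof = max(t.size - 2, 1)
    se = np.sqrt(np.sum(resid**2) / dof / sxx)
    return float(slope), float(se)


def state_slopes(
    times: np.ndarray,
    values: np.ndarray,
    seg: StateSegmentation,
    quantity: str = "dissipation",
    min_points: int = 3,
) -> StateSlopes:
    """OLS slope of a time series within each state, normalized to S1.

    States with fewer than ``min_points`` samples get NaN slopes.  If the S1
    slope is 0 or undefined the normalization is undefined (NaN) but raw
    slopes are still reported.
    """
    labels = seg.state_of_times(times)
    raw, se = {}, {}
    for st in ("S0", "S1", "C"):
        sel = labels == st
        if sel.sum() < min_points:
            raw[st], se[st] = np.nan, np.nan
        else:
            raw[st], se[st] = _ols_slope(np.asarray(times)[sel], np.asarray(values)[sel])
    s1 = raw["S1"]
    if not np.isfinite(s1) or s1 == 0:
        norm = {st: np.nan for st in raw}
    else:
        norm = {st: raw[st] / s1 for st in raw}
    return StateSlopes(raw, se, norm, quantity)


def dissipation_vs_density(
    times: np.ndarray,
    values: np.ndarray,
    density: MyosinDensitySeries,
    seg: StateSegmentation,
    n_rho_bins: int = None,
) -> pd.DataFrame:
    """Pair a curve with myosin density, restricted to state S1.

    The curve is interpolated onto the density time base; S1 frames are
    emitted as (rho, value) rows ordered by rho.  With ``n_rho_bins`` the
    pairs are binned by rho and mean +- sd reported per bin.
    """
    vals_on_rho = np.interp(density.times, np.asarray(times, float), np.asarray(values, float))
    labels = seg.state_of_times(density.times)
    sel = labels == "S1"
    df = pd.DataFrame({"rho_per_um2": density.density[sel], "value": vals_on_rho[sel]})
    df = df.sort_values("rho_per_um2", kind="stable").reset_index(drop=True)
    if n_rho_bins is None:
        return df
    edges = np.linspace(df["rho_per_um2"].min(), df["rho_per_um2"].max(), n_rho_bins + 1)
    idx = np.clip(np.searchsorted(edges, df["rho_per_um2"], side="right") - 1, 0, n_rho_bins - 1)
    g = df.groupby(idx)["value"]
    out = pd.DataFrame(
        {
            "rho_per_um2": 0.5 * (edges[:-1] + edges[1:])[g.mean().index],
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=0).to_numpy(),
            "n": g.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def default_synthetic_config(seed: int = 0) -> dict:
    """Three-state synthetic experiment emulating motor accumulation.

    S0: equilibrium modes (no driving).  S1: nonreciprocal driving alpha = 1
    with the noise temperature ramping 1 -> 3 as motors accumulate (bending
    energy grows).  C: driving reduced to alpha = 0.5 with temperature
    relaxing 3 -> 2.  The myosin count schedule places its onset at the S0/S1
    boundary and its peak at the S1/C boundary.
    """
    return {
        "seed": int(seed),
        "simulate": {
            "n_filaments": 20,
            "dt": 0.01,
            "length_um": 10.0,
            "segments": [
                {"name": "S0", "n_steps": 2000, "k": 1.0, "alpha": 0.0, "temperature": 1.0},
                {"name": "S1", "n_steps": 4000, "k": 1.0, "alpha": 1.0, "temperature": [1.0, 3.0]},
                {"name": "C", "n_steps": 3000, "k": 1.0, "alpha": 0.5, "temperature": [3.0, 2.0]},
            ],
            "myosin": {
                "n_frames": 90,
                "peak_count": 40,
                "end_count": 25,
                "area_um2": 2500.0,
            },
        },
        "entropy": {"bins_per_dim": 12, "min_count": 10},
        "bending": {"EI": geo.ACTIN_EI_PN_UM2, "n_window": 5, "n_points": 50, "subsample": 25},
        "images": {"enabled": False},
    }


def _schedule_segments(sim_cfg: dict):
    segs = []
    for s in sim_cfg["segments"]:
        A = syn.nonreciprocal_drift(float(s["k"]), float(s["alpha"]))
        T = s["temperature"]
        if isinstance(T, (list, tuple)):
            D = (float(T[0]) * np.eye(2), float(T[1]) * np.eye(2))
        else:
            D = float(T) * np.eye(2)
        segs.append({"n_steps": int(s["n_steps"]), "drift": A, "diffusion": D})
    return segs


def _myosin_schedule(sim_cfg: dict, total_time: float) -> MyosinDensitySeries:
    my = sim_cfg["myosin"]
    n = int(my["n_frames"])
    times = np.linspace(0.0, total_time, n)
    steps = [int(s["n_steps"]) for s in sim_cfg["segments"]]
    dt = float(sim_cfg["dt"])
    t_onset = steps[0] * dt
    t_peak = (steps[0] + steps[1]) * dt
    counts = np.zeros(n)
    ramp = (times >= t_onset) & (times < t_peak)
    counts[ramp] = my["peak_count"] * (times[ramp] - t_onset) / (t_peak - t_onset)
    decay = times >= t_peak
    if decay.any():
        frac = (times[decay] - t_peak) / max(total_time - t_peak, 1e-9)
        counts[decay] = my["peak_count"] + (my["end_count"] - my["peak_count"]) * frac
    counts = np.round(counts).astype(int)
    return MyosinDensitySeries(np.arange(n), times, counts, float(my["area_um2"]))


def run_pipeline(config, outdir: str = None) -> dict:
    """Execute the configured analysis chain and return the results bundle.

    ``config`` is a dict or a path to a YAML file (see
    :func:`default_synthetic_config` for the schema).  If ``traces`` is
    configured the mode trajectories come from tracked filament centerlines;
    otherwise they are generated by the activity-schedule Langevin simulator.
    The chain runs modes -> v_ss -> per-filament entropy -> ensemble
    dissipation curve, reconstructed-shape bending energies, myosin-density
    state segmentation, and state-wise slopes; an optional image section
    adds director / order-parameter / spectra / flow outputs.  With
    ``outdir`` all artifacts are written as CSV/JSON plus a provenance
    record; identical config and seed give byte-identical files.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = config
    seed = int(cfg.get("seed", 0))
    results = {"config": cfg}

    # --- mode trajectories -------------------------------------------------
    traces_cfg = cfg.get("traces")
    sim_cfg = cfg.get("simulate")
    if traces_cfg:
        if not os.path.exists(traces_cfg["path"]):
            raise FileNotFoundError(f"trace file not found: {traces_cfg['path']}")
        trajs = geo.read_filament_traces(
            traces_cfg["path"],
            fmt=traces_cfg.get("format", "csv"),
            pixel_size_um=traces_cfg.get("pixel_size_um", 1.0),
            frame_interval_s=traces_cfg.get("frame_interval_s", 1.0),
        )
        trajs = [t for t in trajs if t.usable_for_dynamics]
        n_modes = int(cfg.get("entropy", {}).get("n_modes", 2))
        modes = [geo.modes_from_trajectory(t, n_modes=n_modes) for t in trajs]
        shape_sources = trajs
        total_time = max(float(m.times[-1]) for m in modes)
    elif sim_cfg:
        segs = _schedule_segments(sim_cfg)
        modes = syn.simulate_activity_schedule(
            segs,
            dt=float(sim_cfg["dt"]),
            n_trajectories=int(sim_cfg["n_filaments"]),
            seed=seed,
            length_um=float(sim_cfg["length_um"]),
        )
        shape_sources = None
        total_time = float(modes[0].times[-1])
    else:
        raise ValueError("config must provide either 'traces' or 'simulate'")

    # --- entropy chain -----------------------------------------------------
    ecfg = cfg.get("entropy", {})
    fld = ent.phase_space_velocity_field(
        modes,
        bins_per_dim=int(ecfg.get("bins_per_dim", 12)),
        min_count=int(ecfg.get("min_count", 10)),
    )
    L = modes[0].length
    diffusion = ent.diffusion_matrix_slender_rod(L, n_modes=modes[0].n_modes)
    series = [ent.entropy_production(m, fld, diffusion) for m in modes]
    t_diss, diss = ent.ensemble_dissipation_curve(series)
    results["entropy_series"] = series
    results["dissipation_curve"] = (t_diss, diss)
    results["phase_space_field"] = fld
    results["coverage"] = float(np.mean([s.coverage for s in series]))

    # --- bending energies --------------------------------------------------
    bcfg = cfg.get("bending", {})
    sub = int(bcfg.get("subsample", 25))
    EI = float(bcfg.get("EI", geo.ACTIN_EI_PN_UM2))
    n_window = int(bcfg.get("n_window", 5))
    n_points = int(bcfg.get("n_points", 50))
    if shape_sources is not None:
        bend_t = shape_sources[0].times
        eb = []
        for tr in shape_sources:
            bs = geo.bending_energy_series(tr, EI=EI, n_window=n_window)
            eb.append(np.interp(bend_t, bs.times, bs.energy_per_length))
        eb = np.asarray(eb)
    else:
        bend_t = modes[0].times[::sub]
        eb = np.empty((len(modes), bend_t.size))
        for i, m in enumerate(modes):
            for j, fr in enumerate(range(0, m.n_frames, sub)):
                shp = syn.shape_from_modes(m.amplitudes[fr], L=m.lengths[fr], n_points=n_points)
                _, eps = geo.bending_energy(shp, EI=EI, n_window=n_window)
                eb[i, j] = eps
    bend_curve = eb.mean(axis=0) - eb.mean(axis=0)[0]  # Delta epsilon_bend
    results["bending_curve"] = (bend_t, bend_curve)

    # --- myosin density and state segmentation -----------------------------
    if traces_cfg and "myosin_csv" in traces_cfg:
        dfm = pd.read_csv(traces_cfg["myosin_csv"])
        density = MyosinDensitySeries(
            dfm["frame"].to_numpy(),
            dfm["time_s"].to_numpy(),
            dfm["count"].to_numpy(),
            float(dfm["area_um2"].iloc[0]),
        )
    else:
        density = _myosin_schedule(sim_cfg, total_time)
    seg = segment_states(density)
    slopes_diss = state_slopes(t_diss, diss, seg, quantity="dissipation")
    slopes_bend = state_slopes(bend_t, bend_curve, seg, quantity="bending")
    results["density"] = density
    results["segmentation"] = seg
    results["slopes"] = {"dissipation": slopes_diss, "bending": slopes_bend}
    results["dissipation_vs_density"] = dissipation_vs_density(t_diss, diss, density, seg)
    results["bending_vs_density"] = dissipation_vs_density(bend_t, bend_curve, density, seg)

    # --- optional image chain ----------------------------------------------
    icfg = cfg.get("images", {})
    if icfg.get("enabled"):
        tex = syn.TextureSpec(
            image_shape=tuple(icfg.get("image_shape", (192, 192))),
            pixel_size_um=float(icfg.get("pixel_size_um", 0.2)),
            pattern=("uniform", float(icfg.get("angle_rad", 0.5))),
            noise_sd=float(icfg.get("noise_sd", 0.05)),
            seed=seed + 1,
        )
        img, _ = syn.render_texture(tex)
        df_dir = nem.compute_director_field(img, tex.pixel_size_um)
        df_dir = nem.compute_order_parameter(df_dir)
        spec = density_director_spectra(img, tex.pixel_size_um, df_dir)
        vf = syn.make_velocity_field(("radial", float(icfg.get("inflow_rate", 1e-3))))
        psi = kin.mean_strain_rate([vf])
        results["director_field"] = df_dir
        results["spectra"] = spec
        results["strain_rate"] = psi

    if outdir is not None:
        _write_bundle(results, outdir)
    return results


def _write_bundle(results: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    cfg = results["config"]

    def save_json(name, obj):
        with open(os.path.join(outdir, name), "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

    t, d = results["dissipation_curve"]
    pd.DataFrame({"time_s": t, "dissipation_per_um": d}).to_csv(
        os.path.join(outdir, "dissipation_curve.csv"), index=False
    )
    t, b = results["bending_curve"]
    pd.DataFrame({"time_s": t, "delta_eps_bend": b}).to_csv(
        os.path.join(outdir, "bending_curve.csv"), index=False
    )
    dens = results["density"]
    pd.DataFrame(
        {
            "frame": dens.frames,
            "time_s": dens.times,
            "count": dens.counts,
            "density_per_um2": dens.density,
        }
    ).to_csv(os.path.join(outdir, "myosin_density.csv"), index=False)
    rows = []
    for i, s in enumerate(results["entropy_series"]):
        rows.append(
            {
                "filament": i,
                "final_entropy": s.entropy[-1],
                "final_entropy_per_um": s.entropy_per_length[-1],
                "coverage": s.coverage,
                "low_confidence": bool(s.low_confidence),
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "entropy_summary.csv"), index=False)
    seg = results["segmentation"]
    save_json(
        "segmentation.json",
        {
            "onset_frame": int(seg.onset_frame),
            "peak_frame": int(seg.peak_frame),
            "onset_time_s": seg.onset_time,
            "peak_time_s": seg.peak_time,
            "has_contractile": bool(seg.has_contractile),
            "rho_c_per_um2": seg.rho_c,
        },
    )
    save_json(
        "slopes.json",
        {
            q: {"raw": sl.raw, "stderr": sl.stderr, "normalized": sl.normalized}
            for q, sl in results["slopes"].items()
        },
    )
    fld = results["phase_space_field"]
    save_json(
        "phase_space_field.json",
        {
            "edges": [e.tolist() for e in fld.edges],
            "counts": fld.counts.tolist(),
            "velocity": np.where(np.isfinite(fld.velocity), fld.velocity, None).tolist(),
            "min_count": fld.min_count,
            "n_samples": fld.n_samples,
        },
    )
    results["dissipation_vs_density"].to_csv(
        os.path.join(outdir, "dissipation_vs_density.csv"), index=False
    )
    results["bending_vs_density"].to_csv(
        os.path.join(outdir, "bending_vs_density.csv"), index=False
    )
    from . import __version__

    save_json(
        "provenance.json",
        {
            "package_version": __version__,
            "config": cfg,
            "coverage": results["coverage"],
        },
    )
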