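"""Estimate entropy production from bending-mode trajectories.

Simulates an ensemble of 2-mode Langevin trajectories with a nonreciprocal
coupling (alpha = 1) that breaks detailed balance, coarse-grains the
phase-space velocity, integrates the entropy along each trajectory and
compares the recovered rate with the exact Lyapunov closed form 2*alpha^2/k.
"""

import numpy as np

import actent as ae

spec = ae.LangevinSpec(
    drift_matrix=ae.nonreciprocal_drift(k=1.0, alpha=1.0),
    diffusion_matrix=np.eye(2),
    dt=0.005,
    n_steps=50_000,
    n_trajectories=20,
    seed=0,
)
trajs = ae.simulate_mode_dynamics(spec)
field = ae.phase_space_velocity_field(trajs, bins_per_dim=12, min_count=10)
D = ae.DiffusionModel(np.eye(2))
series = [ae.entropy_production(m, field, D) for m in trajs]

rate = np.mean([s.entropy[-1] / s.times[-1] for s in series])
oracle = ae.ou_entropy_rate(spec.drift_matrix, spec.diffusion_matrix)
windows = ae.windowed_entropy_samples(series, 200)
slope, ci = ae.check_detailed_fluctuation_theorem(windows)

print(f"estimated entropy production rate : {rate:.3f} per unit time")
print(f"Lyapunov closed-form rate         : {oracle:.3f}")
print(f"DFT slope ln[P(+dS)/P(-dS)] vs dS : {slope:.3f}  (95% CI {ci[0]:.3f}..{ci[1]:.3f})")
print("A rate near the closed form and a DFT slope near 1 mean the")
print("coarse-grained estimator is quantitatively capturing the broken")
print("detailed balance of the driven mode dynamics.")
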