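"""Decompose a filament shape into bending modes and measure its bending energy.

Builds a gently curved 10 um filament from prescribed mode amplitudes,
recovers the amplitudes from the point representation, and integrates the
squared rolling-circle curvature into a bending energy.
"""

import numpy as np

import actent as ae
import actent.geometry as geo

true_amps = np.array([0.25, -0.10])
shape = ae.shape_from_modes(true_amps, L=10.0, n_points=100, mean_angle=0.3)

recovered = geo.decompose_modes(shape, n_modes=4)
kappa = geo.local_curvature(shape, n_window=5)
E, eps = geo.bending_energy(shape, EI=geo.ACTIN_EI_PN_UM2, n_window=5)

print(f"prescribed amplitudes : {true_amps}")
print(f"recovered amplitudes  : {np.round(recovered, 6)}")
print(f"max |curvature|       : {np.nanmax(np.abs(kappa)):.4f} 1/um")
print(f"bending energy E_bend : {E:.3e} pN um   (eps_bend = {eps:.3e} pN)")
print("The first two recovered amplitudes match the prescribed ones to")
print("machine precision; higher modes are zero because the shape contains")
print("no higher-order bends.")
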