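"""Full synthetic three-state experiment: S0 -> S1 -> C slope analysis.

Runs the default synthetic experiment (equilibrium modes, then nonreciprocal
driving with rising noise temperature while the myosin count ramps, then
reduced driving past the density peak), segments the states from the myosin
density series, and reports dissipation and bending-energy slopes normalized
to state S1.
"""

import numpy as np

import actent as ae

results = ae.run_pipeline(ae.default_synthetic_config(seed=0))

seg = results["segmentation"]
print(f"state boundaries: S1 starts at t = {seg.onset_time:.1f} s, "
      f"C at t = {seg.peak_time:.1f} s (rho_c = {seg.rho_c:.4f} /um^2)")
print(f"mean phase-space coverage: {results['coverage']:.3f}")
for quantity in ("dissipation", "bending"):
    sl = results["slopes"][quantity].normalized
    print(f"{quantity:12s} slopes (normalized to S1): "
          f"S0 = {sl['S0']:+.3f}, S1 = {sl['S1']:.3f}, C = {sl['C']:+.3f}")
print("Both quantities rise fastest in the active non-contractile state S1:")
print("the entropy production rate is maximal before contraction sets in.")
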