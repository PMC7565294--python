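"""Forward model: diffusion weighting and multi-pool echo attenuation.

Builds the default constant-gradient protocol (G = 24 T/m, 20 encoding times
0.02-0.6 ms, 15 mixing times 0.2-40 ms), prints the b-value range it reaches,
and evaluates the three-pool attenuation curve at one mixing time.
"""

import numpy as np

from tddc import default_protocol, forward_attenuation, yeast_truth

protocol = default_protocol()
print(f"tau grid: {len(protocol.tau_grid)} steps, "
      f"{protocol.tau_grid[0]*1e3:.2f}-{protocol.tau_grid[-1]*1e3:.2f} ms")
print(f"tm grid:  {len(protocol.tm_grid)} values, "
      f"{protocol.tm_grid[0]*1e3:.1f}-{protocol.tm_grid[-1]*1e3:.0f} ms")
print(f"max b = {protocol.max_b():.3e} s/m^2  "
      "(the weighting that separates organelle water from cytoplasm)")

tm = 5e-3
comps = yeast_truth().compartments_at(tm)
print(f"\npools at tm = {tm*1e3:.0f} ms (D in 1e-9 m^2/s, apparent fraction):")
for D, p in zip(comps.D, comps.p):
    print(f"  D = {D/1e-9:6.4f}   p = {p:.4f}")

E = forward_attenuation(protocol, comps, protocol.tau_grid, tm,
                        reference_normalized=True)
print("\nE/E0 over the tau grid (first/last 3):",
      np.round(E[:3], 4), "...", np.round(E[-3:], 4))
print("Each pool contributes exp(-b*D_i); the fast extracellular pool is "
      "gone after a few points, the organelle pool persists to the largest b.")
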