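"""Full TDDC analysis: interval fitting + compartment characterisation.

Synthesizes a noisy dataset at the study conditions, fits every mixing time
with the interval strategy (three-pool fits at short t_m, windowed two-pool
fits once the extracellular signal is gone), then extracts bulk
diffusivities, surface-to-volume ratios, sizes, lifetimes and membrane
permeabilities per compartment.
"""

from tddc import (
    characterize,
    default_protocol,
    default_yeast_plan,
    interval_strategy_series,
    yeast_truth,
)
from tddc.synthetic import generate

protocol = default_protocol()
truth = yeast_truth(noise_sigma=0.005, seed=1)
dataset = generate(truth, protocol)

series = interval_strategy_series(dataset)
summary = characterize(series, default_yeast_plan())

cols = ["comp", "D0_1e-9_m2s", "SV_per_um", "p0", "tau_s", "R_um", "Pd_um_s"]
print(summary.to_frame()[cols].round(4).to_string(index=False))
print(
    "\ncomp 1 = extracellular water, 2 = cytoplasm, 3 = organelle pool.\n"
    "Generating truth: D02 = 0.692, D03 = 0.095 (x1e-9 m^2/s); "
    "R2 = 2.252 um, R3 = 0.277 um;\n"
    "tau2 = 0.39 s, tau3 = 0.039 s, hence P_d2 = 1.92 um/s and "
    "P_d3 = 2.37 um/s.\n"
    "At 0.5% noise the localization sizes (R2, R3) and the cytoplasmic D02 "
    "are the\nrobust columns; D01, D03 and the lifetimes are "
    "information-limited on a single\ndataset (the 40 ms window resolves "
    "only a tenth of tau2), so their single-run\nvalues scatter — run "
    "several seeds or consult the uncertainty columns."
)
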