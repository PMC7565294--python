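"""Per-mixing-time fitting and AIC model comparison.

Generates one noisy synthetic dataset, fits the two-pool-plus-intercept
model (model 1) and the three-pool model (model 2) to an intermediate
mixing time, and compares them with Akaike weights.
"""

from tddc import (
    FitConfig,
    akaike_weights,
    default_protocol,
    fit_attenuation,
    yeast_truth,
)
from tddc.synthetic import generate

protocol = default_protocol()
dataset = generate(yeast_truth(noise_sigma=0.005, seed=3), protocol)

i = 8  # tm ~ 4.1 ms: all three pools attenuate measurably
tm = float(protocol.tm_grid[i])
curve = dataset.curve(i)

r1 = fit_attenuation(curve, protocol, FitConfig(model_id="model1"), tm=tm)
r2 = fit_attenuation(curve, protocol, FitConfig(model_id="model2"), tm=tm)

print(f"mixing time {tm*1e3:.2f} ms, {r1.N} points")
for res in (r1, r2):
    Ds = ", ".join(f"{d/1e-9:.3f}" for d in res.estimates.D)
    print(f"{res.model_id}: D = [{Ds}] x1e-9 m^2/s   "
          f"RSS = {res.RSS:.2e}  AIC = {res.AIC:.1f}")
w1, w2 = akaike_weights([r1.AIC, r2.AIC])
print(f"Akaike weights: model1 {w1:.3f} vs model2 {w2:.3f}")
print("The three-pool model carries (almost) all of the weight: at this "
      "mixing time the slow organelle pool attenuates too much to be a "
      "constant offset.")
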