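"""Monte-Carlo power curve for the PAC test, and effect-size conversion.

Power at each candidate slope is the fraction of simulated studies (full
design redrawn each replicate) in which the 1-df PAC likelihood-ratio test
rejects at alpha 0.05.  Slopes are translated to correlation coefficients
via r = slope * SD_PAC / SD_RTL so they can be compared across species.

Replicates are kept small here so the example runs in a couple of minutes;
the acceptance script runs the full-size version.
"""

from soaytel import (
    PowerRequest,
    estimate_power,
    minimum_detectable_effect,
    r_to_slope,
    slope_to_r,
    study_design,
)

print(f"slope 0.012 -> r = {slope_to_r(0.012):.3f} (human-scale effect)")
print(f"r 0.378 -> slope = {r_to_slope(0.378):.4f} (chimpanzee-scale effect)")

req = PowerRequest(structure=study_design(),
                   effect_grid=(0.0, 0.006, 0.012, 0.033),
                   n_reps=60, alpha=0.05, seed=2)
ests = estimate_power(req)
for e in ests:
    print(f"slope {e.effect:+.3f} (r {slope_to_r(e.effect):+.3f}): "
          f"power {e.power:5.1%} +- {e.mc_se:.1%}")

mde = minimum_detectable_effect(ests, target_power=0.8)
print(f"minimum detectable slope at 80% power: ~{mde.slope:.4f} "
      f"(interpolated between {mde.bracket[0]} and {mde.bracket[1]})")
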