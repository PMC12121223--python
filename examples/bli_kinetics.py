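"""Globally fit BLI sensorgrams and compute the affinity fold-change.

Simulates glypican-4 binding traces for the triple mutant at the published
rates (kon = 0.42 1/(uM*s), koff = 0.15 1/s) at 0.2/0.4/0.8 uM with 1%
noise, refits all three traces jointly, and compares the resulting K_D with
the published scaffold affinity.
"""

from fgfhs import fold_change, global_fit, simulate_sensorgram
from fgfhs.reference import PUBLISHED_KINETICS
from fgfhs.synthetic import SyntheticSpec

kon, _, koff, _, _, _ = PUBLISHED_KINETICS["FGF1_HS_BCD"]
traces = simulate_sensorgram(kon, koff, rmax=1.0, spec=SyntheticSpec(seed=42))
fit = global_fit(traces)

print("global fit of three concentrations (0.2/0.4/0.8 uM, 1% noise):")
print(f"  kon  = {fit.kon[0]:.3f} 1/(uM*s)   (simulated with {kon})")
print(f"  koff = {fit.koff[0]:.3f} 1/s        (simulated with {koff})")
print(f"  K_D  = {fit.kd_reported:.3f} uM")

kd_hs = PUBLISHED_KINETICS["FGF1_HS"][4]
gain = fold_change(kd_hs, fit.kd_reported)
print(f"\nagainst the published scaffold K_D of {kd_hs} uM this is a "
      f"{gain:.1f}-fold affinity gain (> 20-fold).")
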