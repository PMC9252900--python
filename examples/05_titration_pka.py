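"""Fit the pH dependence of transient-absorption amplitudes.

The amplitude of the hot-ground-state feature titrates with pH; a
Henderson-Hasselbalch sigmoid with Hill coefficient 1 models a single
protonatable group (a histidine near the chromophore pocket, pKa ~7.2).
"""

import numpy as np

import photokin as pk

ph = np.linspace(6.6, 8.4, 8)
series = pk.simulate_titration(pka=7.2, a_low=0.2, a_high=3.2,
                               ph_values=ph, noise_sigma=0.15, seed=2)

fit = pk.fit_pka(series)
print(f"fitted pKa = {fit.pka:.2f} +/- {fit.pka_err:.2f} (truth 7.2)")
print(f"plateaus: a_low = {fit.a_low:.2f}, a_high = {fit.a_high:.2f} mOD")
print(f"flags: extrapolated={fit.extrapolated}, "
      f"ill_conditioned={fit.ill_conditioned}")

print("\npH    measured   model")
for p, a in zip(series.ph_values, series.amplitudes):
    print(f"{p:4.2f}  {a:8.3f}  {fit.model(p):8.3f}")
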