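"""Estimate the photoisomerization quantum yield from the carbonyl bleach.

Right after excitation the ring-D carbonyl bleach (1,684 cm^-1) counts all
excited molecules; once the reaction is over only the isomerized fraction
is still missing from the ground state. The ratio of fitted late/early
bleach amplitudes is the yield.
"""

import photokin as pk

wn, early, late = pk.simulate_bleach_pair(isomerization_fraction=0.33,
                                          noise_sigma=0.1, seed=3)

bleach = pk.SpectralBand("bleach", 1684.0, 13.0, -4.0)
excited = pk.SpectralBand("ES", 1666.0, 14.0, 3.0)
product = pk.SpectralBand("product", 1692.0, 13.0, 1.0)

qy, qy_err, fit_early, fit_late = pk.qy_from_bleach_ratio(
    (wn, early), (wn, late), bleach,
    early_companions=[excited], late_companions=[product],
)

print(f"early bleach amplitude: {fit_early.bands[0].amplitude:7.3f} mOD")
print(f"late  bleach amplitude: {fit_late.bands[0].amplitude:7.3f} mOD")
print(f"quantum yield = {100 * qy:.1f} +/- {100 * qy_err:.1f} % "
      f"(generator truth 33%)")
print("\nband widths are shared between the early and late fits; the yield")
print("is invariant under a common rescaling of both spectra.")
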