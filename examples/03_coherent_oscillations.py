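"""Extract the coherent-oscillation doublet from a global-fit residual.

Wavepacket motion survives the multiexponential fit as damped cosines in
the residual; the dominant doublet here sits at 300 and 340 cm^-1 with
~160 fs damping, the signature of chromophore out-of-plane modes.
"""

import numpy as np

import photokin as pk
from photokin.oscillations import kinetic_background_basis

scheme = pk.default_scheme_pfr()
irf = pk.InstrumentResponse(fwhm=40.0, t0=0.0)
delays = np.concatenate([np.arange(-0.2, 2.5, 0.01),
                         np.geomspace(2.55, 15.0, 40)])
wavenumbers = np.linspace(10000.0, 16500.0, 60)
bands = pk.default_bands_vis()

with_osc = pk.simulate_ta(scheme, bands, delays, wavenumbers, irf,
                          oscillations=pk.default_oscillations(),
                          noise=pk.NoiseSpec(0.008, seed=5))

fit = pk.global_fit(with_osc, 4, init=[0.05, 0.15, 1.5, 4.0], irf=irf)
t, residual = pk.residual_trace(with_osc, fit, wavenumber=12435.0, t_max=2.2)

# the exponential fit absorbs part of the oscillation; co-fitting its basis
# as nuisance regressors deconfounds the oscillation parameters
background = kinetic_background_basis(fit, t)
osc_fit = pk.fit_damped_cosines(t, residual, n_components=2, irf=irf,
                                background=background)
print("damped-cosine components of the residual at 12,435 cm^-1")
print("(generator truth: 300 and 340 cm^-1, 160 fs damping):")
for c, sig in zip(osc_fit.components, osc_fit.significant):
    print(f"  {c.frequency:6.1f} cm^-1, damping {c.damping_time:6.0f} fs, "
          f"amplitude {c.amplitude:.3f} mOD, significant={bool(sig)}")

nu, power = pk.residual_power_map(t, residual[:, None])
print(f"\ndiagnostic FFT power map peaks at {nu[np.argmax(power[0])]:.0f} cm^-1")
print("(the time-domain fit separates the doublet; the ~2 ps window makes")
print("the FFT view coarse, which is why it is diagnostic only)")
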