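"""Coherent-oscillation analysis of global-fit residuals.

After the multiexponential kinetics are removed, wavepacket dynamics survive
as damped cosine oscillations in the residual. The primary estimator here is
a time-domain damped-cosine fit (the dominant 300/340 cm^-1 doublet beats at
~0.8 ps and is poorly separated by an FFT over a ~2 ps, 160-fs-damped
window); a windowed FFT power map is provided as a diagnostic view.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dataset import TADataset
from .kinetics import GlobalFitResult, InstrumentResponse, irf_kernel_complex
from .simulate import C_CM_PER_FS, OscillationComponent

__all__ = [
    "residual_trace",
    "fit_damped_cosines",
    "residual_power_map",
    "kinetic_background_basis",
    "DampedCosineFit",
]


def kinetic_background_basis(fit: GlobalFitResult, delays_ps) -> np.ndarray:
    """Exponential-basis time courses of a global fit, for use as nuisance
    regressors in :func:`fit_damped_cosines`.

    Whatever part of a residual the kinetic fit could have absorbed lies in
    the span of these columns; including them deconfounds oscillation
    parameters from kinetic misfit.
    """
    from .kinetics import _design_matrix

    return _design_matrix(fit.time_constants, np.asarray(delays_ps, float),
                          fit.irf, fit.offset_spectrum is not None)


def residual_trace(data: TADataset, fit: GlobalFitResult, wavenumber: float,
                   t_max: float | None = None):
    """Data minus fitted model at the nearest probe pixel.

    The trace is cropped to ``[t0, t_max]`` (t0 from the fit's IRF) so the
    pre-excitation region does not enter oscillation fitting. Returns
    ``(delays_ps, residual)``.
    """
    wn = data.wavenumbers
    if not (min(wn) <= wavenumber <= max(wn)):
        raise ValueError(f"wavenumber {wavenumber} outside the probe axis")
    j = data.wn_index(wavenumber)
    res = data.values[:, j] - fit.model[:, j]
    t0 = fit.irf.t0_ps
    hi = data.delays.max() if t_max is None else t_max
    if hi < t0:
        raise ValueError("t_max is earlier than time zero")
    m = (data.delays >= t0) & (data.delays <= hi)
    return data.delays[m], res[m]


@dataclass
class DampedCosineFit:
    """Damped-cosine decomposition of a residual trace."""

    components: list            # OscillationComponent, sorted by frequency
    amplitude_errors: np.ndarray
    significant: np.ndarray     # bool: amplitude > 3x residual rms
    cost: float
    residual: np.ndarray
    n_starts: int
    converged: bool
    start_table: list           # (init frequencies, cost) per multi-start


def _cosine_design(t_fs, freqs_cm, taus_fs, irf=None, t_ps=None):
    """Columns [Re g, -Im g] per mode; g is the (optionally IRF-convolved)
    complex damped exponential, so amplitudes/phases stay linear."""
    cols = []
    for nu, tau in zip(freqs_cm, taus_fs):
        if irf is None:
            env = np.exp(-t_fs / tau)
            arg = 2.0 * np.pi * C_CM_PER_FS * nu * t_fs
            cols.append(env * np.cos(arg))
            cols.append(-env * np.sin(arg))
        else:
            kappa = 1e3 / tau - 1j * (2.0 * np.pi * C_CM_PER_FS * nu * 1e3)
            g = irf_kernel_complex(t_ps, kappa, irf)
            cols.append(np.real(g))
            cols.append(-np.imag(g))
    return np.column_stack(cols)


def fit_damped_cosines(
    delays_ps,
    trace,
    n_components: int,
    freq_range: tuple = (100.0, 700.0),
    n_freq_seeds: int = 12,
    tau_init_fs: float | None = None,
    irf: InstrumentResponse | None = None,
    background: np.ndarray | None = None,
) -> DampedCosineFit:
    """Least-squares fit of a sum of damped cosines to a residual trace.

    Model: sum_i A_i exp(-t/tau_i) cos(2 pi c nu_i t + phi_i) with
    c = 2.9979e-5 cm/fs. Amplitude and phase are linear (solved exactly per
    evaluation); frequency and damping are optimized by nonlinear least
    squares from a deterministic multi-start: every ``n_components``-subset
    of ``n_freq_seeds`` log-spaced frequency seeds over ``freq_range``, plus
    an FFT-peak-based start. The best cost is kept; components are returned
    sorted by frequency.

    When ``irf`` is given, each basis function is the analytic Gaussian-IRF
    convolution of the damped cosine (complex-rate kernel), so traces that
    include the pump-probe onset are fitted without waveform bias.

    ``background`` may hold nuisance time courses (n_points x k columns,
    e.g. from :func:`kinetic_background_basis`) that are co-fitted linearly;
    they absorb kinetic misfit that would otherwise bias the oscillation
    parameters.
    """
    t_ps = np.asarray(delays_ps, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t_ps.size != y.size:
        raise ValueError("delays and trace lengths differ")
    if y.size < 4 * n_components:
        raise ValueError("trace too short for the requested number of components")
    t_fs = (t_ps - t_ps[0]) * 1e3
    span_fs = max(t_fs[-1], 1.0)
    if tau_init_fs is None:
        tau_init_fs = span_fs / 5.0

    bg = None
    if background is not None:
        bg = np.atleast_2d(np.asarray(background, dtype=float))
        if bg.shape[0] != t_ps.size:
            bg = bg.T
        if bg.shape[0] != t_ps.size:
            raise ValueError("background columns must match the trace length")

    def design(freqs, taus):
        X = _cosine_design(t_fs, freqs, taus, irf=irf, t_ps=t_ps)
        return X if bg is None else np.hstack([X, bg])

    def model_resid(x):
        freqs = x[:n_components]
        taus = np.exp(x[n_components:])
        X = design(freqs, taus)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ coef

    # FFT-peak start
    fft_seeds = None
    if y.size >= 8:
        dt_fs = np.median(np.diff(t_fs))
        tu = np.arange(t_fs[0], t_fs[-1] + dt_fs / 2, dt_fs)
        yu = np.interp(tu, t_fs, y)
        power = np.abs(np.fft.rfft(yu * np.hanning(yu.size), n=4 * yu.size)) ** 2
        nu_axis = np.fft.rfftfreq(4 * yu.size, d=dt_fs) / C_CM_PER_FS
        inside = (nu_axis >= freq_range[0]) & (nu_axis <= freq_range[1])
        if inside.sum() > n_components:
            idx = np.argsort(power[inside])[::-1][:n_components]
            fft_seeds = np.sort(nu_axis[inside][idx])

    seeds = np.geomspace(freq_range[0], freq_range[1], n_freq_seeds)
    starts = [np.asarray(c, float)
              for c in itertools.combinations(seeds, n_components)]
    if fft_seeds is not None and len(fft_seeds) == n_components:
        starts.insert(0, fft_seeds)

    lb = np.concatenate([np.full(n_components, 1.0),
                         np.full(n_components, np.log(2.0))])
    ub = np.concatenate([np.full(n_components, 0.5 / (C_CM_PER_FS *
                                                      np.median(np.diff(t_fs)))),
                         np.full(n_components, np.log(50.0 * span_fs))])
    best, table = None, []
    for f0 in starts:
        x0 = np.concatenate([f0, np.full(n_components, np.log(tau_init_fs))])
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(model_resid, x0, bounds=(lb, ub), x_scale="jac")
        except (np.linalg.LinAlgError, ValueError):
            continue
        table.append((tuple(np.round(f0, 1)), float(2 * sol.cost)))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("damped-cosine fit failed for every start; "
                           f"multi-start table: {table}")

    freqs = best.x[:n_components]
    taus = np.exp(best.x[n_components:])
    X = design(freqs, taus)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma = float(np.std(resid))

    comps, amps = [], []
    for i in range(n_components):
        a, b = coef[2 * i], coef[2 * i + 1]
        A = float(np.hypot(a, b))
        phi = float(np.arctan2(b, a))
        comps.append(OscillationComponent(float(freqs[i]), float(taus[i]),
                                          phase=phi, amplitude=A))
        amps.append(A)
    order = np.argsort([c.frequency for c in comps])
    comps = [comps[i] for i in order]
    amps = np.asarray(amps)[order]
    significant = amps > 3.0 * sigma
    return DampedCosineFit(
        components=comps,
        amplitude_errors=np.full(n_components, sigma),
        significant=significant,
        cost=float(np.sum(resid**2)),
        residual=resid,
        n_starts=len(starts),
        converged=bool(best.success),
        start_table=table,
    )


def residual_power_map(
    delays_ps,
    residuals,
    window: str | None = "hann",
    zero_pad: int = 4,
):
    """Windowed DFT of the residual along delay, per probe pixel.

    ``residuals`` is (n_t, n_wn); non-uniform delay grids are resampled to
    the median spacing. Returns ``(nu_osc_cm, power)`` with power shaped
    (n_wn, n_freq). With ``window=None`` and ``zero_pad=1`` Parseval's
    identity (sum |x|^2 = mean |X|^2) holds to machine precision.
    """
    t = np.asarray(delays_ps, dtype=float)
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    if R.shape[0] != t.size:
        R = R.T
    if t.size < 8:
        raise ValueError("need at least 8 time points")
    dt = np.median(np.diff(t))
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        tu = np.arange(t[0], t[-1] + dt / 2, dt)
        R = np.stack([np.interp(tu, t, R[:, j]) for j in range(R.shape[1])], axis=1)
        t = tu
    n = t.size
    w = np.hanning(n) if window == "hann" else np.ones(n)
    nfft = int(zero_pad) * n
    F = np.fft.rfft(R * w[:, None], n=nfft, axis=0)
    dt_fs = dt * 1e3
    nu = np.fft.rfftfreq(nfft, d=dt_fs) / C_CM_PER_FS
    power = (np.abs(F) ** 2).T
    return nu, power
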