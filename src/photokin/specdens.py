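"""Spectral power density of dipole-moment trajectories.

Linear response relates the imaginary dielectric susceptibility to the
equilibrium autocorrelation C(t) = <p(t) . p(0)> of the total dipole moment:

    chi''(omega) = omega / (2 k_B T V eps0) * C(omega),

with C(omega) the Fourier transform of C(t), T the temperature, V an
effective system volume and eps0 the vacuum permittivity. The quantity
reported is the spectral power density omega * chi''(omega) on a wavenumber
axis. Input conventions: dipole in e*Angstrom, time step in fs, volume in
nm^3; internal conversions are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "DipoleTrajectory",
    "SusceptibilitySpectrum",
    "dipole_autocorrelation",
    "spectral_power_density",
    "compare_isotopologue_spectra",
]

# conversion constants (6 significant figures)
_E_ANGSTROM_TO_CM = 1.60218e-29     # e*A -> C*m
_KB = 1.38065e-23                   # J/K
_EPS0 = 8.85419e-12                 # F/m
_C_CM_PER_FS = 2.99792e-5           # cm/fs


@dataclass
class DipoleTrajectory:
    """Uniformly sampled total-dipole time series.

    ``dipole`` has shape (n, 3) in e*Angstrom, ``dt`` in fs, ``temperature``
    in K and ``volume`` (the effective volume entering the susceptibility
    normalisation) in nm^3.
    """

    dt: float
    dipole: np.ndarray
    temperature: float = 300.0
    volume: float = 0.3
    isotope_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dipole = np.asarray(self.dipole, dtype=float)
        if self.dipole.ndim != 2 or self.dipole.shape[1] != 3:
            raise ValueError("dipole must have shape (n, 3)")
        if self.dipole.shape[0] < 16:
            raise ValueError("trajectory must contain at least 16 samples")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.volume > 0:
            raise ValueError("volume must be > 0")

    @property
    def n_samples(self) -> int:
        return self.dipole.shape[0]

    @property
    def span(self) -> float:
        """Trajectory span in fs."""
        return (self.n_samples - 1) * self.dt

    def truncated(self, t_skip_fs: float) -> "DipoleTrajectory":
        """Drop the initial ``t_skip_fs`` (fast-equilibration) segment."""
        n_skip = int(round(t_skip_fs / self.dt))
        if self.n_samples - n_skip < 16:
            raise ValueError("truncation leaves fewer than 16 samples")
        return DipoleTrajectory(self.dt, self.dipole[n_skip:], self.temperature,
                                self.volume, self.isotope_label, dict(self.meta))


def dipole_autocorrelation(traj: DipoleTrajectory, max_lag: float | None = None):
    """Unbiased vector autocorrelation C(t) = <p(t' + t) . p(t')>.

    ``max_lag`` is in fs and must stay below half the trajectory span.
    Returns ``(lags_fs, C)`` with C(0) = <|p|^2> in (e*A)^2.
    """
    n = traj.n_samples
    if max_lag is None:
        max_lag = traj.span / 2.0
    n_lag = int(max_lag / traj.dt) + 1
    if n_lag > n // 2 + 1:
        raise ValueError("max_lag exceeds half the trajectory span")
    # FFT-based correlation per component, unbiased normalisation
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    acf = np.zeros(n_lag)
    for c in range(3):
        x = traj.dipole[:, c]
        F = np.fft.rfft(x, n=nfft)
        full = np.fft.irfft(F * np.conj(F), n=nfft)[:n_lag]
        acf += full
    counts = n - np.arange(n_lag)
    acf /= counts
    lags = np.arange(n_lag) * traj.dt
    return lags, acf


@dataclass
class SusceptibilitySpectrum:
    """omega * chi''(omega) on a uniform wavenumber axis starting at zero."""

    frequency_axis: np.ndarray      # cm^-1
    power: np.ndarray               # omega * chi''(omega), dimensionless * rad/s
    autospectrum: np.ndarray        # two-sided C(omega) in (e*A)^2 fs
    segments_averaged: int
    temperature: float
    volume: float
    isotope_label: str = ""
    meta: dict = field(default_factory=dict)


def spectral_power_density(
    traj: DipoleTrajectory,
    n_segments: int = 4,
    window: str = "hann",
    truncate_fs: float = 0.0,
) -> SusceptibilitySpectrum:
    """Segment-averaged spectral power density omega * chi''(omega).

    The dipole power spectrum C(omega) is estimated per Cartesian component
    with Welch's method (``n_segments`` half-overlapping segments, Hann
    window by default) and summed over components; the susceptibility
    prefactor omega/(2 k_B T V eps0) is applied in SI units and the axis is
    converted to cm^-1. ``window="boxcar"`` with ``n_segments=1`` gives the
    plain (Parseval-consistent) periodogram.
    """
    if truncate_fs > 0:
        traj = traj.truncated(truncate_fs)
    n = traj.n_samples
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    nperseg = n if n_segments == 1 else int(2 * n / (n_segments + 1))
    nperseg = max(min(nperseg, n), 8)
    fs = 1.0 / traj.dt  # 1/fs
    psd = None
    for c in range(3):
        f, p = _signal.welch(
            traj.dipole[:, c], fs=fs, window=window, nperseg=nperseg,
            noverlap=nperseg // 2, detrend=False, scaling="density",
            return_onesided=True,
        )
        psd = p if psd is None else psd + p
    # one-sided density -> two-sided C(omega); welch doubles interior bins
    two_sided = psd.copy()
    interior = slice(1, None if nperseg % 2 else -1)
    two_sided[interior] = two_sided[interior] / 2.0

    # susceptibility prefactor in SI
    f_hz = f * 1e15
    omega = 2.0 * np.pi * f_hz
    c_si = two_sided * _E_ANGSTROM_TO_CM**2 * 1e-15      # C^2 m^2 s
    chi_im = omega * c_si / (2.0 * _KB * traj.temperature
                             * traj.volume * 1e-27 * _EPS0)
    power = omega * chi_im
    nu_cm = f / _C_CM_PER_FS
    n_seg_eff = 1 if n_segments == 1 else max(
        1, (n - nperseg) // (nperseg - nperseg // 2) + 1)
    return SusceptibilitySpectrum(
        frequency_axis=nu_cm, power=power, autospectrum=two_sided,
        segments_averaged=n_seg_eff, temperature=traj.temperature,
        volume=traj.volume, isotope_label=traj.isotope_label,
        meta={"nperseg": nperseg, "window": window, "dt_fs": traj.dt},
    )


def compare_isotopologue_spectra(
    a: SusceptibilitySpectrum,
    b: SusceptibilitySpectrum,
    window: tuple = (1750.0, 1900.0),
) -> dict:
    """Normalisation-invariant similarity of two spectra over a window.

    Reports the L2 distance between amplitude-normalised spectra, the ratio
    of integrated power (b over a) and the centroid shift (b minus a) over
    the window (default: the continuum-band region 1,750-1,900 cm^-1).
    The two spectra are linearly resampled onto their common grid first.
    """
    lo, hi = min(window), max(window)
    lo_c = max(lo, a.frequency_axis.min(), b.frequency_axis.min())
    hi_c = min(hi, a.frequency_axis.max(), b.frequency_axis.max())
    if hi_c <= lo_c:
        raise ValueError("window is disjoint from the common frequency axis")
    step = min(np.median(np.diff(a.frequency_axis)),
               np.median(np.diff(b.frequency_axis)))
    grid = np.arange(lo_c, hi_c + step / 2, step)
    pa = np.interp(grid, a.frequency_axis, a.power)
    pb = np.interp(grid, b.frequency_axis, b.power)
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na == 0 or nb == 0:
        dist = 0.0 if na == nb else float("inf")
    else:
        dist = float(np.linalg.norm(pa / na - pb / nb))
    ia, ib = np.trapezoid(pa, grid), np.trapezoid(pb, grid)
    ratio = float(ib / ia) if ia != 0 else float("inf")

    def centroid(p):
        tot = np.trapezoid(np.abs(p), grid)
        return float(np.trapezoid(grid * np.abs(p), grid) / tot) if tot > 0 else float("nan")

    return {
        "normalized_l2_distance": dist,
        "integrated_power_ratio": ratio,
        "centroid_shift": centroid(pb) - centroid(pa),
        "window": (float(lo_c), float(hi_c)),
        "n_points": int(grid.size),
    }
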