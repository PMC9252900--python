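"""Polarization channel algebra, anisotropy and transition-dipole angles.

For a single pumped electronic transition probed by a band whose transition
dipole moment (TDM) makes an angle theta with the pumped TDM,

    r = (par - per) / (par + 2 per) = 0.2 (3 cos^2 theta - 1),

so r spans [-0.2, 0.4] and vanishes at the magic angle (54.74 deg). The
isotropic channel is iso = (par + 2 per)/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import TADataset

__all__ = [
    "AnisotropyTrace",
    "isotropic",
    "anisotropy",
    "angle_from_anisotropy",
    "estimate_noise",
]

MAGIC_ANGLE_DEG = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))


def estimate_noise(values: np.ndarray) -> float:
    """Robust per-point noise sigma from second differences along delay.

    For a signal that is smooth on the delay grid, the second difference of
    consecutive points is dominated by noise with variance 6 sigma^2; the
    median absolute value gives an outlier-resistant estimate.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 3:
        return float(np.std(v))
    d2 = np.diff(v, n=2, axis=0)
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def isotropic(par: TADataset, per: TADataset) -> TADataset:
    """Magic-angle-equivalent channel iso = (par + 2 per)/3."""
    if not par.same_grids(per):
        raise ValueError("par and per datasets have different grids")
    return TADataset(par.delays.copy(), par.wavenumbers.copy(),
                     (par.values + 2.0 * per.values) / 3.0,
                     channel="iso", meta={**per.meta, **par.meta})


@dataclass
class AnisotropyTrace:
    """Band-averaged time-resolved anisotropy and derived TDM angle."""

    delays: np.ndarray
    r: np.ndarray                    # r(t), NaN where masked
    band_window: tuple
    masked_fraction: float
    r_mean: float
    r_err: float
    theta: float                     # degrees
    theta_err: float
    delay_window: tuple
    out_of_range: bool               # r_mean outside [-0.2, 0.4]
    meta: dict = field(default_factory=dict)


def anisotropy(
    par: TADataset,
    per: TADataset,
    band_window: tuple,
    delay_window: tuple = (0.4, 0.6),
    noise_sigma: float | None = None,
) -> AnisotropyTrace:
    """Time-resolved anisotropy of a band window, with TDM-angle inversion.

    r is computed per point as (par - per)/(par + 2 per); points whose
    denominator magnitude is below 3x the per-point noise sigma are masked
    (and counted), then r is averaged over ``band_window`` per delay. The
    angle is inverted from the mean r over ``delay_window`` with a
    first-order (delta-method) error. Values of r outside [-0.2, 0.4] are
    flagged, not clamped.
    """
    if not par.same_grids(per):
        raise ValueError("par and per datasets have different grids")
    wmask = (par.wavenumbers >= min(band_window)) & (par.wavenumbers <= max(band_window))
    if not wmask.any():
        raise ValueError("band_window selects no pixels")
    p = par.values[:, wmask]
    s = per.values[:, wmask]
    denom = p + 2.0 * s
    if noise_sigma is None:
        noise_sigma = max(estimate_noise(p), estimate_noise(s))
    thresh = 3.0 * 3.0 ** 0.5 * noise_sigma  # 3 sigma of the denominator
    ok = np.abs(denom) > thresh
    masked_fraction = float(1.0 - ok.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        r_pt = np.where(ok, (p - s) / denom, np.nan)
    valid = np.isfinite(r_pt)
    counts = valid.sum(axis=1)
    sums = np.where(valid, r_pt, 0.0).sum(axis=1)
    r_t = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    tmask = ((par.delays >= min(delay_window)) & (par.delays <= max(delay_window))
             & np.isfinite(r_t))
    if not tmask.any():
        raise ValueError("delay_window selects no usable delays")
    rw = r_t[tmask]
    r_mean = float(np.mean(rw))
    r_err = float(np.std(rw, ddof=1) / np.sqrt(rw.size)) if rw.size > 1 else 0.0
    out = not (-0.2 <= r_mean <= 0.4)
    if out:
        theta = theta_err = float("nan")
    else:
        theta, theta_err = angle_from_anisotropy(r_mean, r_err)
    return AnisotropyTrace(
        delays=par.delays.copy(), r=r_t, band_window=tuple(band_window),
        masked_fraction=masked_fraction, r_mean=r_mean, r_err=r_err,
        theta=theta, theta_err=theta_err, delay_window=tuple(delay_window),
        out_of_range=out,
        meta={"noise_sigma": noise_sigma, "n_delays_averaged": int(tmask.sum())},
    )


def angle_from_anisotropy(r: float, r_err: float = 0.0):
    """Invert r = 0.2 (3 cos^2 theta - 1) to theta in degrees.

    The error is propagated to first order (delta method); it diverges at
    the endpoints r = 0.4 (theta = 0) and r = -0.2 (theta = 90).
    Returns ``(theta_deg, theta_err_deg)``.
    """
    if not (-0.2 <= r <= 0.4):
        raise ValueError(f"anisotropy r={r} outside the invertible range [-0.2, 0.4]")
    u2 = (5.0 * r + 1.0) / 3.0
    u = np.sqrt(np.clip(u2, 0.0, 1.0))
    theta = float(np.degrees(np.arccos(u)))
    if r_err == 0.0:
        return theta, 0.0
    s2 = 1.0 - u2
    if s2 <= 0.0 or u == 0.0:
        return theta, float("inf")
    dtheta_dr = (5.0 / 6.0) / (u * np.sqrt(s2))  # |d theta / d r| in rad
    return theta, float(np.degrees(dtheta_dr * r_err))
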