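"""Band decomposition of IR difference spectra, the bleach-ratio quantum-yield
estimator, continuum-band transients, and Henderson-Hasselbalch pKa fitting.

The quantum yield of photoproduct formation is estimated from the carbonyl
bleach of pyrrole ring D: immediately after excitation the bleach amplitude
counts every excited molecule, while after the reaction is completed only the
isomerized fraction has not returned to the parent state. The ratio of the
late to the early fitted bleach amplitude is the yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.ndimage import median_filter

from .dataset import TADataset
from .simulate import BandShape, SpectralBand, TitrationSeries

__all__ = [
    "BandFit",
    "TitrationFit",
    "fit_band_model",
    "qy_from_bleach_ratio",
    "continuum_band_transient",
    "fit_pka",
]


@dataclass
class BandFit:
    """Least-squares refinement of a band template against one spectrum."""

    bands: list                      # fitted SpectralBand copies
    errors: list                     # dict per band: 1-sigma for free params
    baseline: float
    baseline_error: float
    cost: float
    residual: np.ndarray
    result: object = None            # underlying lmfit.MinimizerResult

    def model(self, wavenumbers) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        out = np.full(wn.shape, self.baseline)
        for b in self.bands:
            out = out + b.amplitude * b.profile(wn)
        return out


_FREE_DEFAULT = frozenset({"amplitude", "center", "fwhm"})


def fit_band_model(wavenumbers, spectrum, template, free=None,
                   baseline: bool = True) -> BandFit:
    """Refine a band template against a measured spectrum.

    ``template`` is a list of :class:`SpectralBand`; ``free`` optionally
    gives, per band, the subset of {"amplitude", "center", "fwhm"} to vary
    (default: all three). Fixed parameters are left untouched. A constant
    baseline offset is free by default (IR baselines drift).

    Every (non-plateau) template center must lie within the spectral range
    extended by 2 fwhm, otherwise the band is unconstrained and an error is
    raised.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if wn.size != y.size:
        raise ValueError("wavenumbers and spectrum lengths differ")
    lo, hi = wn.min(), wn.max()
    for b in template:
        if b.shape is BandShape.flat_plateau:
            continue
        if not (lo - 2 * b.fwhm <= b.center <= hi + 2 * b.fwhm):
            raise ValueError(
                f"template band {b.label!r} at {b.center} cm^-1 lies more than "
                f"2 fwhm outside the spectral range [{lo}, {hi}]"
            )
    if free is None:
        free = [_FREE_DEFAULT] * len(template)
    if len(free) != len(template):
        raise ValueError("free mask list length must match template")

    params = lmfit.Parameters()
    for i, (b, fr) in enumerate(zip(template, free)):
        params.add(f"amp_{i}", value=b.amplitude, vary="amplitude" in fr)
        params.add(f"cen_{i}", value=b.center, vary="center" in fr,
                   min=lo - 2 * b.fwhm, max=hi + 2 * b.fwhm)
        params.add(f"fwhm_{i}", value=b.fwhm, vary="fwhm" in fr, min=1e-6)
    params.add("baseline", value=0.0, vary=baseline)

    profiles = list(template)

    def model_of(p):
        out = np.full(wn.shape, p["baseline"].value)
        for i, b in enumerate(profiles):
            bb = replace(b, amplitude=1.0, center=p[f"cen_{i}"].value,
                         fwhm=p[f"fwhm_{i}"].value)
            out = out + p[f"amp_{i}"].value * bb.profile(wn)
        return out

    def resid(p):
        return model_of(p) - y

    result = lmfit.minimize(resid, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"band fit did not converge: {result.message}")
    p = result.params
    fitted, errors = [], []
    for i, b in enumerate(template):
        fitted.append(replace(b, amplitude=p[f"amp_{i}"].value,
                              center=p[f"cen_{i}"].value,
                              fwhm=p[f"fwhm_{i}"].value))
        errors.append({
            "amplitude": p[f"amp_{i}"].stderr,
            "center": p[f"cen_{i}"].stderr,
            "fwhm": p[f"fwhm_{i}"].stderr,
        })
    r = np.asarray(result.residual, dtype=float)
    return BandFit(
        bands=fitted, errors=errors,
        baseline=p["baseline"].value,
        baseline_error=p["baseline"].stderr or 0.0,
        cost=float(np.sum(r**2)), residual=-r, result=result,
    )


def qy_from_bleach_ratio(
    early,
    late,
    bleach_band: SpectralBand,
    early_companions=(),
    late_companions=(),
    mode: str = "amplitude",
):
    """Photoproduct quantum yield from the early/late bleach amplitude ratio.

    ``early`` and ``late`` are ``(wavenumbers, spectrum)`` pairs. The early
    spectrum is fitted with the bleach plus its early companions (e.g. the
    downshifted excited-state carbonyl); the late spectrum with the bleach
    plus its late companions (e.g. the blueshifted photoproduct band), with
    all band widths fixed to the early-fit values (the shared-width
    assumption of same-mode bands). QY = |late bleach| / |early bleach|,
    with first-order error propagation from both fits. ``mode="area"``
    ratios amplitude x fwhm instead.

    Returns ``(qy, qy_err, early_fit, late_fit)``.
    """
    wn_e, y_e = np.asarray(early[0], float), np.asarray(early[1], float)
    wn_l, y_l = np.asarray(late[0], float), np.asarray(late[1], float)
    for wn in (wn_e, wn_l):
        if not (wn.min() <= bleach_band.center <= wn.max()):
            raise ValueError("both spectra must cover the bleach band")
    template_e = [bleach_band, *early_companions]
    fit_e = fit_band_model(wn_e, y_e, template_e)
    # widths shared early <-> late and fixed during the late fit
    bleach_fitted = fit_e.bands[0]
    template_l = [replace(bleach_band, fwhm=bleach_fitted.fwhm), *late_companions]
    free_l = [{"amplitude", "center"}] * len(template_l)
    fit_l = fit_band_model(wn_l, y_l, template_l, free=free_l)

    a_e, a_l = fit_e.bands[0].amplitude, fit_l.bands[0].amplitude
    s_e = fit_e.errors[0]["amplitude"] or 0.0
    s_l = fit_l.errors[0]["amplitude"] or 0.0
    if abs(a_e) <= 2.0 * s_e or a_e == 0.0:
        raise ValueError("early bleach amplitude is consistent with zero")
    if mode == "area":
        w_e, w_l = fit_e.bands[0].fwhm, fit_l.bands[0].fwhm
        qy = abs(a_l * w_l) / abs(a_e * w_e)
    elif mode == "amplitude":
        qy = abs(a_l) / abs(a_e)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rel = np.sqrt((s_e / a_e) ** 2 + ((s_l / a_l) ** 2 if a_l != 0 else 0.0))
    return float(qy), float(abs(qy) * rel), fit_e, fit_l


def continuum_band_transient(
    data: TADataset,
    window: tuple = (1772.0, 1832.0),
    smooth: int | None = 5,
):
    """Mean continuum-band signal per delay over a wavenumber window.

    The default window, 1,772-1,832 cm^-1, sits inside the broad continuum
    band of the proton-loaded water network. Optional moving-median
    smoothing (odd width) gives a presentation trace; the raw trace is
    always returned. Returns ``(delays, raw, smoothed_or_None)``.
    """
    wmask = (data.wavenumbers >= min(window)) & (data.wavenumbers <= max(window))
    if not wmask.any():
        raise ValueError("window selects no pixels")
    raw = data.values[:, wmask].mean(axis=1)
    smoothed = None
    if smooth is not None:
        if smooth % 2 == 0 or smooth < 1:
            raise ValueError("smooth width must be odd and positive")
        smoothed = median_filter(raw, size=smooth, mode="nearest")
    return data.delays.copy(), raw, smoothed


@dataclass
class TitrationFit:
    """Henderson-Hasselbalch fit of an amplitude-vs-pH series (Hill = 1)."""

    pka: float
    pka_err: float
    a_low: float
    a_high: float
    a_low_err: float
    a_high_err: float
    extrapolated: bool          # pKa outside sampled range +/- 1 unit
    ill_conditioned: bool       # plateau separation below noise
    cost: float
    result: object = None
    meta: dict = field(default_factory=dict)

    def model(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.a_low + (self.a_high - self.a_low) / (1.0 + 10.0 ** (self.pka - ph))


def fit_pka(series: TitrationSeries) -> TitrationFit:
    """Weighted least-squares Henderson-Hasselbalch fit with fixed Hill = 1.

    amplitude(pH) = a_low + (a_high - a_low)/(1 + 10^(pKa - pH)). Requires
    at least 4 pH points spanning more than 1 pH unit. Uncertainties come
    from the local curvature of the cost; a fitted pKa outside the sampled
    range by more than 1 unit is flagged extrapolated, and a plateau
    separation below 3x the residual noise is flagged ill-conditioned.
    """
    ph, amp = series.ph_values, series.amplitudes
    if ph.size < 4:
        raise ValueError("need at least 4 pH points")
    if ph.max() - ph.min() <= 1.0:
        raise ValueError("pH range must span more than 1 unit")
    weights = None
    if series.errors is not None and np.all(series.errors > 0):
        weights = 1.0 / series.errors

    params = lmfit.Parameters()
    params.add("pka", value=float(np.median(ph)))
    params.add("a_low", value=float(amp[0]))
    params.add("a_high", value=float(amp[-1]))

    def resid(p):
        m = p["a_low"].value + (p["a_high"].value - p["a_low"].value) / (
            1.0 + 10.0 ** (p["pka"].value - ph))
        r = m - amp
        return r * weights if weights is not None else r

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    span = abs(p["a_high"].value - p["a_low"].value)
    resid_rms = float(np.std(np.asarray(result.residual)))
    scale = float(np.mean(series.errors)) if weights is not None else 1.0
    ill = span < 3.0 * resid_rms * scale or (p["pka"].stderr or np.inf) > (
        ph.max() - ph.min())
    extrap = not (ph.min() - 1.0 <= p["pka"].value <= ph.max() + 1.0)
    return TitrationFit(
        pka=p["pka"].value, pka_err=p["pka"].stderr or float("nan"),
        a_low=p["a_low"].value, a_high=p["a_high"].value,
        a_low_err=p["a_low"].stderr or float("nan"),
        a_high_err=p["a_high"].stderr or float("nan"),
        extrapolated=extrap, ill_conditioned=bool(ill),
        cost=float(np.sum(np.asarray(result.residual) ** 2)),
        result=result,
        meta={"n_points": int(ph.size), "ph_range": (float(ph.min()), float(ph.max()))},
    )
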