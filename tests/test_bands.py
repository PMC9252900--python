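"""IR band fitting, bleach-ratio quantum yield, CB transient, pKa fitting."""

import numpy as np
import pytest

import photokin as pk
from photokin.simulate import BLEACH, band_matrix


def _spectrum(bands, wn, sigma=0.0, seed=0):
    y = band_matrix(bands, wn).sum(axis=0)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, sigma, wn.size)
    return y


def test_self_fit_is_exact():
    wn = np.arange(1640.0, 1721.0, 1.0)
    truth = [pk.SpectralBand("b", 1684.0, 12.0, -4.0),
             pk.SpectralBand("e", 1666.0, 15.0, 2.5)]
    fit = pk.fit_band_model(wn, _spectrum(truth, wn), truth)
    assert np.abs(fit.residual).max() < 1e-9
    for got, want in zip(fit.bands, truth):
        assert got.center == pytest.approx(want.center, abs=1e-6)
        assert got.amplitude == pytest.approx(want.amplitude, abs=1e-6)
        assert got.fwhm == pytest.approx(want.fwhm, abs=1e-6)


def test_product_band_center_recovered():
    # ELF-region pair: propC bleach at 1,743 and product band at 1,735 cm^-1
    wn = np.arange(1700.0, 1761.0, 1.0)
    truth = [pk.SpectralBand("bleach", 1743.0, 10.0, -2.0),
             pk.SpectralBand("prod", 1735.0, 10.0, 1.1)]
    y = _spectrum(truth, wn, sigma=0.02, seed=4)
    template = [pk.SpectralBand("bleach", 1745.0, 10.0, -1.5),
                pk.SpectralBand("prod", 1730.0, 10.0, 0.8)]
    fit = pk.fit_band_model(wn, y, template)
    assert fit.bands[1].center == pytest.approx(1735.0, abs=1.0)


def test_band_outside_range_rejected():
    wn = np.arange(1700.0, 1761.0, 1.0)
    bad = [pk.SpectralBand("far", 1600.0, 10.0, 1.0)]
    with pytest.raises(ValueError, match="outside the spectral range"):
        pk.fit_band_model(wn, np.zeros(wn.size), bad)


def test_fixed_parameters_untouched():
    wn = np.arange(1640.0, 1721.0, 1.0)
    truth = [pk.SpectralBand("b", 1684.0, 12.0, -4.0)]
    y = _spectrum(truth, wn)
    template = [pk.SpectralBand("b", 1684.0, 9.0, -1.0)]
    fit = pk.fit_band_model(wn, y, template, free=[{"amplitude"}])
    assert fit.bands[0].fwhm == 9.0
    assert fit.bands[0].center == 1684.0


def test_band_fit_cost_never_exceeds_input_norm():
    wn = np.arange(1640.0, 1721.0, 1.0)
    truth = [pk.SpectralBand("b", 1684.0, 12.0, -4.0)]
    y = _spectrum(truth, wn, sigma=0.05, seed=1)
    template = [pk.SpectralBand("b", 1680.0, 14.0, -2.0)]
    fit = pk.fit_band_model(wn, y, template)
    assert np.linalg.norm(fit.residual) <= np.linalg.norm(y)


# ---------------------------------------------------------------------------
# Bleach-ratio quantum yield
# ---------------------------------------------------------------------------


def _qy_templates():
    bleach = pk.SpectralBand("bleach", 1684.0, 13.0, -4.0)
    es = pk.SpectralBand("ES", 1666.0, 14.0, 3.0)
    prod = pk.SpectralBand("product", 1692.0, 13.0, 1.0)
    return bleach, es, prod


def test_qy_unity_when_late_equals_early():
    wn, early, _ = pk.simulate_bleach_pair(1.0)
    bleach, es, prod = _qy_templates()
    # same companion band (generator width 13 * 1.1) in both fits
    es_exact = pk.SpectralBand("ES", 1666.0, 14.3, 3.0)
    qy, err, *_ = pk.qy_from_bleach_ratio((wn, early), (wn, early.copy()), bleach,
                                          early_companions=[es_exact],
                                          late_companions=[es_exact])
    assert qy == pytest.approx(1.0, abs=1e-6)


def test_qy_zero_for_vanished_bleach():
    wn, early, _ = pk.simulate_bleach_pair(0.5)
    bleach, es, prod = _qy_templates()
    qy, *_ = pk.qy_from_bleach_ratio((wn, early), (wn, np.zeros_like(early)),
                                     bleach, early_companions=[es],
                                     late_companions=[prod])
    assert qy == pytest.approx(0.0, abs=1e-6)


def test_qy_recovery_over_noise_seeds():
    bleach, es, prod = _qy_templates()
    values = []
    for seed in range(20):
        wn, early, late = pk.simulate_bleach_pair(0.33, noise_sigma=0.1, seed=seed)
        qy, *_ = pk.qy_from_bleach_ratio((wn, early), (wn, late), bleach,
                                         early_companions=[es],
                                         late_companions=[prod])
        values.append(qy)
    assert np.mean(values) == pytest.approx(0.33, abs=0.07)


def test_qy_invariant_under_common_rescaling():
    bleach, es, prod = _qy_templates()
    wn, early, late = pk.simulate_bleach_pair(0.4, noise_sigma=0.05, seed=3)
    q1, *_ = pk.qy_from_bleach_ratio((wn, early), (wn, late), bleach,
                                     early_companions=[es], late_companions=[prod])
    q2, *_ = pk.qy_from_bleach_ratio((wn, 7.5 * early), (wn, 7.5 * late), bleach,
                                     early_companions=[es], late_companions=[prod])
    assert q2 == pytest.approx(q1, rel=1e-6)


def test_qy_rejects_zero_early_bleach():
    wn = np.arange(1630.0, 1721.0, 1.0)
    bleach, es, prod = _qy_templates()
    noise = np.random.default_rng(0).normal(0, 0.01, wn.size)
    with pytest.raises(ValueError, match="consistent with zero"):
        pk.qy_from_bleach_ratio((wn, noise), (wn, noise), bleach,
                                early_companions=[es], late_companions=[prod])


# ---------------------------------------------------------------------------
# Continuum-band transient
# ---------------------------------------------------------------------------


def test_cb_transient_window_and_smoothing(make_ir_dataset):
    ds = make_ir_dataset(sigma=0.05, seed=2)
    t, raw, smooth = pk.continuum_band_transient(ds, window=(1772.0, 1832.0),
                                                 smooth=5)
    assert raw.shape == t.shape and smooth.shape == t.shape
    assert raw[t > 0.3].max() > 0.3  # CB rises within ~300 fs
    with pytest.raises(ValueError, match="no pixels"):
        pk.continuum_band_transient(ds, window=(5000.0, 6000.0))
    with pytest.raises(ValueError, match="odd"):
        pk.continuum_band_transient(ds, smooth=4)


def test_cb_absent_without_cb_band(scheme, ir_irf):
    delays = pk.default_delays()
    wn = np.arange(1630.0, 1921.0, 2.5)
    bands = [b for b in pk.default_bands_ir() if b.label != "CB"]
    ds = pk.simulate_ta(scheme, bands, delays, wn, ir_irf,
                        noise=pk.NoiseSpec(0.05, 5))
    _, raw, _ = pk.continuum_band_transient(ds, window=(1772.0, 1832.0))
    n_pix = ((ds.wavenumbers >= 1772) & (ds.wavenumbers <= 1832)).sum()
    assert np.abs(raw).max() < 5 * 0.05 / np.sqrt(n_pix)


def test_cb_decay_time_matches_deprotonated_branch(make_ir_dataset):
    from scipy.optimize import curve_fit

    ds = make_ir_dataset()
    t, raw, _ = pk.continuum_band_transient(ds, smooth=None)
    m = t > 0.8
    popt, _ = curve_fit(lambda t, a, tau: a * np.exp(-t / tau), t[m], raw[m],
                        p0=[1.0, 1.0])
    assert popt[1] == pytest.approx(1.5, abs=0.2)


# ---------------------------------------------------------------------------
# Titration fit
# ---------------------------------------------------------------------------


def test_pka_noiseless_fit_is_sharp():
    ph = np.linspace(6.6, 8.4, 8)
    series = pk.simulate_titration(7.2, -0.5, 3.5, ph)
    fit = pk.fit_pka(series)
    assert fit.pka == pytest.approx(7.2, abs=1e-6)
    assert not fit.extrapolated
    assert not fit.ill_conditioned


def test_pka_recovery_with_noise():
    ph = np.linspace(6.6, 8.4, 8)
    span = 4.0
    out = []
    for seed in range(10):
        series = pk.simulate_titration(7.2, 0.0, span, ph,
                                       noise_sigma=0.05 * span, seed=seed)
        out.append(pk.fit_pka(series).pka)
    assert np.mean(out) == pytest.approx(7.2, abs=0.3)


def test_flat_series_flagged_ill_conditioned():
    ph = np.linspace(6.0, 9.0, 8)
    rng = np.random.default_rng(1)
    series = pk.TitrationSeries(ph, 2.0 + rng.normal(0, 0.05, 8),
                                np.full(8, 0.05))
    fit = pk.fit_pka(series)
    assert fit.ill_conditioned


def test_pka_shift_equivariance():
    ph = np.linspace(6.6, 8.4, 8)
    series = pk.simulate_titration(7.2, -1.0, 2.0, ph, noise_sigma=0.1, seed=6)
    base = pk.fit_pka(series).pka
    delta = 0.7
    shifted = pk.TitrationSeries(series.ph_values + delta, series.amplitudes,
                                 series.errors)
    assert pk.fit_pka(shifted).pka == pytest.approx(base + delta, abs=1e-6)


def test_pka_preconditions():
    with pytest.raises(ValueError, match="4 pH points"):
        pk.fit_pka(pk.TitrationSeries([6.0, 7.0, 8.0], [0, 1, 2]))
    with pytest.raises(ValueError, match="span"):
        pk.fit_pka(pk.TitrationSeries([7.0, 7.2, 7.4, 7.6], [0, 1, 2, 3]))
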