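"""Forward simulator: causality, linearity, channels, titration, Langevin."""

import numpy as np
import pytest

import photokin as pk
from photokin.simulate import BLEACH, band_matrix


def test_causality_zero_before_time_zero(scheme, irf, vis_grid):
    delays, wn = vis_grid
    band = [pk.SpectralBand("a", 12000, 800, 3.0, compartment="S1")]
    ds = pk.simulate_ta(scheme, band, delays, wn, irf)
    early = delays < irf.t0_ps - 7 * irf.sigma_ps
    assert early.any()
    assert np.abs(ds.values[early]).max() < 1e-9


def test_linearity_in_bands(scheme, irf, vis_grid):
    delays, wn = vis_grid
    bands = pk.default_bands_vis()
    a, b = bands[:4], bands[4:]
    full = pk.simulate_ta(scheme, bands, delays, wn, irf)
    da = pk.simulate_ta(scheme, a, delays, wn, irf)
    db = pk.simulate_ta(scheme, b, delays, wn, irf)
    assert np.allclose(full.values, da.values + db.values, atol=1e-12)


def test_reproducibility_same_seed(make_vis_dataset):
    d1 = make_vis_dataset(sigma=0.1, seed=42)
    d2 = make_vis_dataset(sigma=0.1, seed=42)
    assert np.array_equal(d1.values, d2.values)
    d3 = make_vis_dataset(sigma=0.1, seed=43)
    assert not np.array_equal(d1.values, d3.values)


def test_polarization_closure(make_vis_dataset):
    out = make_vis_dataset(channel="both")
    iso = (out["par"].values + 2 * out["per"].values) / 3.0
    assert np.allclose(iso, out["iso"].values, atol=1e-15)
    direct = make_vis_dataset(channel="iso")
    assert np.allclose(out["iso"].values, direct.values, atol=1e-12)


def test_magic_angle_bands_have_no_dichroism(scheme, irf, vis_grid):
    delays, wn = vis_grid
    theta_m = pk.MAGIC_ANGLE_DEG
    bands = [pk.SpectralBand("a", 12000, 800, 3.0, compartment="S1",
                             tdm_angle=theta_m),
             pk.SpectralBand("g", 13000, 700, -2.0, compartment=BLEACH,
                             tdm_angle=theta_m)]
    out = pk.simulate_ta(scheme, bands, delays, wn, irf, channel="both")
    assert np.allclose(out["par"].values, out["per"].values, atol=1e-12)
    assert np.allclose(out["par"].values, out["iso"].values, atol=1e-12)


def test_late_spectrum_contains_only_product_and_bleach(scheme, irf):
    # at 15 ps the deprotonated-branch population is e^(-10) ~ 4.5e-5 and
    # GS* has cooled to ~2% -- ELF(+) and bleach(-) dominate
    delays = np.array([-0.2, 0.1, 15.0])
    wn = np.linspace(10000, 16500, 120)
    bands = pk.default_bands_vis()
    ds = pk.simulate_ta(scheme, bands, delays, wn, irf)
    late = ds.values[-1]
    elf_frac = pk.overall_quantum_yield(scheme, "ELF")
    truth = (band_matrix([b for b in bands if b.compartment == "ELF"], wn).sum(axis=0)
             + band_matrix([b for b in bands if b.compartment == BLEACH], wn).sum(axis=0)
             ) * elf_frac
    # excited-state contamination below 3% of peak (GS* tail dominates the rest)
    assert np.max(np.abs(late - truth)) < 0.03 * np.abs(ds.values).max()
    C = pk.concentration_profiles(scheme, irf, delays)
    es = C[[scheme.states.index(s) for s in ("S1", "ES_prot", "ES_deprot")], -1]
    assert np.all(es < 1e-4)


def test_unknown_compartment_rejected(scheme, irf, vis_grid):
    delays, wn = vis_grid
    bad = [pk.SpectralBand("x", 12000, 500, 1.0, compartment="Nowhere")]
    with pytest.raises(ValueError, match="compartment"):
        pk.simulate_ta(scheme, bad, delays, wn, irf)


def test_non_monotone_grid_rejected(scheme, irf):
    wn = np.array([1.0, 3.0, 2.0])
    with pytest.raises(ValueError, match="strictly increasing"):
        pk.simulate_ta(scheme, [], np.array([0.0, 1.0]), wn,
                       irf)


def test_band_invariants():
    with pytest.raises(ValueError, match="fwhm"):
        pk.SpectralBand("b", 1700, -1.0, 1.0)
    with pytest.raises(ValueError, match="edges"):
        pk.SpectralBand("b", 1800, 100, 1.0, shape="flat_plateau")
    with pytest.raises(ValueError, match="tdm_angle"):
        pk.SpectralBand("b", 1700, 10, 1.0, tdm_angle=120.0)


# ---------------------------------------------------------------------------
# Titration generator
# ---------------------------------------------------------------------------


def test_titration_midpoint_and_asymptotes():
    s = pk.simulate_titration(7.2, -1.0, 5.0, [7.2], noise_sigma=0.0)
    assert s.amplitudes[0] == pytest.approx(2.0)  # (a_low + a_high)/2
    lo = pk.simulate_titration(7.2, -1.0, 5.0, [-20.0], noise_sigma=0.0)
    hi = pk.simulate_titration(7.2, -1.0, 5.0, [40.0], noise_sigma=0.0)
    assert lo.amplitudes[0] == pytest.approx(-1.0, abs=1e-9)
    assert hi.amplitudes[0] == pytest.approx(5.0, abs=1e-9)


def test_noiseless_titration_refits_exactly():
    ph = np.linspace(6.6, 8.4, 8)
    series = pk.simulate_titration(7.2, 0.5, 4.0, ph, noise_sigma=0.0)
    fit = pk.fit_pka(series)
    assert fit.pka == pytest.approx(7.2, abs=1e-6)


# ---------------------------------------------------------------------------
# Langevin dipole generator
# ---------------------------------------------------------------------------


def test_langevin_zero_coupling_is_silent():
    traj = pk.langevin_dipole_trajectory(300.0, 50.0, 0.0, dt=1.0, n_steps=100,
                                         seed=0)
    assert np.all(traj.dipole == 0.0)


def test_langevin_deterministic_in_seed():
    a = pk.langevin_dipole_trajectory(300.0, 50.0, 0.5, dt=1.0, n_steps=500, seed=7)
    b = pk.langevin_dipole_trajectory(300.0, 50.0, 0.5, dt=1.0, n_steps=500, seed=7)
    assert np.array_equal(a.dipole, b.dipole)


def test_langevin_underdamped_autocorrelation_oscillates():
    # friction << omega0: C(t) ~ cos(omega0 t) envelope; first zero crossing
    # of the autocorrelation near a quarter period
    traj = pk.langevin_dipole_trajectory(300.0, 15.0, 0.5, dt=1.0,
                                         n_steps=60000, seed=2)
    lags, C = pk.dipole_autocorrelation(traj, max_lag=400.0)
    period_fs = 1.0 / (pk.simulate.C_CM_PER_FS * 300.0)  # ~111 fs
    first_min = lags[np.argmin(C[lags <= period_fs])]
    assert first_min == pytest.approx(period_fs / 2, rel=0.1)


def test_langevin_equipartition_variance():
    traj = pk.langevin_dipole_trajectory(600.0, 200.0, 0.8, dt=0.5,
                                         n_steps=120000, seed=3,
                                         temperature=300.0)
    std = traj.dipole.std(axis=0)
    assert np.allclose(std, 0.8, rtol=0.1)
    hot = pk.langevin_dipole_trajectory(600.0, 200.0, 0.8, dt=0.5,
                                        n_steps=120000, seed=3,
                                        temperature=1200.0)
    assert hot.dipole.std() == pytest.approx(1.6, rel=0.1)


def test_langevin_rejects_bad_steps():
    with pytest.raises(ValueError, match="dt"):
        pk.langevin_dipole_trajectory(300.0, 50.0, 1.0, dt=0.0, n_steps=100)
    with pytest.raises(ValueError, match="n_steps"):
        pk.langevin_dipole_trajectory(300.0, 50.0, 1.0, dt=1.0, n_steps=2)


def test_oscillation_component_time_course():
    osc = pk.OscillationComponent(300.0, 160.0, phase=0.0, amplitude=2.0)
    t = np.array([-0.5, 0.0, 0.16])
    y = osc.evaluate(t)
    assert y[0] == 0.0
    assert y[1] == pytest.approx(2.0)
    assert abs(y[2]) <= 2.0 * np.exp(-1.0) + 1e-9
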