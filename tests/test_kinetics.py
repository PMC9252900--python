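"""Compartment kinetics: analytic solution, quantum yields, global fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import photokin as pk
from photokin.kinetics import _varpro_solve, irf_kernel


# ---------------------------------------------------------------------------
# Scheme structure and quantum yields
# ---------------------------------------------------------------------------


def test_default_scheme_structure(scheme):
    assert scheme.branching["ES_deprot"] == {"ELF": 0.7, "GS*": 0.3}
    assert scheme.branching["S1"] == {"ES_prot": 0.5, "ES_deprot": 0.5}
    for src, out in scheme.branching.items():
        assert sum(out.values()) == pytest.approx(1.0)
    assert set(scheme.terminal_states) == {"ELF", "S0"}


def test_scheme_validation_rejects_bad_input():
    with pytest.raises(ValueError, match="sums to"):
        pk.CompartmentScheme(["A", "B"], {"A": 1.0}, {"A": {"B": 0.5}}, {"A": 1.0})
    with pytest.raises(ValueError, match="cycle"):
        pk.CompartmentScheme(
            ["A", "B"], {"A": 1.0, "B": 2.0},
            {"A": {"B": 1.0}, "B": {"A": 1.0}}, {"A": 1.0},
        )
    with pytest.raises(ValueError, match="unknown"):
        pk.overall_quantum_yield(pk.default_scheme_pfr(), "nope")


def test_overall_quantum_yield_elf(scheme):
    # single forward path: 0.5 bifurcation x 0.7 isomerization branch
    assert pk.overall_quantum_yield(scheme, "ELF") == pytest.approx(0.35, abs=1e-12)


def test_quantum_yield_unique_sink_is_one():
    s = pk.CompartmentScheme(
        ["A", "B", "C"], {"A": 0.1, "B": 1.0},
        {"A": {"B": 1.0}, "B": {"C": 1.0}}, {"A": 1.0},
    )
    assert pk.overall_quantum_yield(s, "C") == pytest.approx(1.0)


def test_terminal_yields_sum_to_one(scheme):
    total = sum(pk.overall_quantum_yield(scheme, s) for s in scheme.terminal_states)
    assert total == pytest.approx(1.0, abs=1e-12)


def _random_acyclic_scheme(rng, n_states=8):
    states = [f"s{i}" for i in range(n_states)]
    lifetimes, branching = {}, {}
    for i in range(n_states - 2):  # last two stay terminal
        targets = rng.choice(np.arange(i + 1, n_states),
                             size=min(2, n_states - i - 1), replace=False)
        fracs = rng.dirichlet(np.ones(len(targets)))
        lifetimes[states[i]] = float(rng.uniform(0.05, 5.0))
        branching[states[i]] = {states[j]: float(f) for j, f in zip(targets, fracs)}
    return pk.CompartmentScheme(states, lifetimes, branching, {states[0]: 1.0})


def _enumerate_path_yield(scheme, product):
    """Brute-force oracle: explicit enumeration of every path to the product."""
    total = 0.0
    stack = [(s, p) for s, p in scheme.initial_population.items()]
    while stack:
        state, weight = stack.pop()
        if state == product:
            total += weight
            continue
        for dst, frac in scheme.branching.get(state, {}).items():
            stack.append((dst, weight * frac))
    return total


@pytest.mark.parametrize("trial", range(5))
def test_quantum_yield_matches_path_enumeration(trial):
    rng = np.random.default_rng(100 + trial)
    s = _random_acyclic_scheme(rng)
    for product in s.terminal_states:
        assert pk.overall_quantum_yield(s, product) == pytest.approx(
            _enumerate_path_yield(s, product), abs=1e-12)


# ---------------------------------------------------------------------------
# Concentration profiles
# ---------------------------------------------------------------------------


def test_single_state_sharp_irf_limit():
    s = pk.CompartmentScheme(["A"], {}, {}, {"A": 1.0})
    # terminal single state: step function
    t = np.linspace(-1, 5, 200)
    C = pk.concentration_profiles(s, None, t)
    assert np.allclose(C[0, t >= 0], 1.0)
    assert np.allclose(C[0, t < 0], 0.0)

    s2 = pk.CompartmentScheme(["A", "B"], {"A": 0.8}, {"A": {"B": 1.0}}, {"A": 1.0})
    C2 = pk.concentration_profiles(s2, None, t)
    expected = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / 0.8), 0.0)
    assert np.allclose(C2[0], expected, atol=1e-12)


def test_population_conservation(scheme, irf):
    t = np.linspace(-0.5, 20.0, 400)
    C = pk.concentration_profiles(scheme, irf, t)
    total = C.sum(axis=0)
    after = t > irf.t0_ps + 5 * irf.sigma_ps
    assert np.max(np.abs(total[after] - 1.0)) < 1e-9


def _ode_oracle(scheme, irf, delays):
    """Adaptive numerical integration of dc/dt = K c + IRF(t) e_init."""
    K = scheme.rate_matrix()
    c0_dir = np.array([scheme.initial_population.get(s, 0.0) for s in scheme.states])
    s_ps, t0 = irf.sigma_ps, irf.t0_ps

    def rhs(t, c):
        pump = np.exp(-((t - t0) ** 2) / (2 * s_ps**2)) / (s_ps * np.sqrt(2 * np.pi))
        return K @ c + pump * c0_dir

    t_start = t0 - 8 * s_ps
    sol = solve_ivp(rhs, (t_start, delays.max()), np.zeros(len(scheme.states)),
                    t_eval=delays[delays >= t_start], rtol=1e-10, atol=1e-12,
                    method="LSODA")
    out = np.zeros((len(scheme.states), delays.size))
    out[:, delays >= t_start] = sol.y
    return out


def test_profiles_match_numeric_ode(scheme, irf):
    delays = np.linspace(-0.2, 15.0, 120)
    analytic = pk.concentration_profiles(scheme, irf, delays)
    numeric = _ode_oracle(scheme, irf, delays)
    assert np.max(np.abs(analytic - numeric)) < 1e-6


def test_degenerate_rates_perturbed_not_failed(irf):
    s = pk.CompartmentScheme(
        ["A", "B", "C"], {"A": 1.0, "B": 1.0},
        {"A": {"B": 1.0}, "B": {"C": 1.0}}, {"A": 1.0},
    )
    delays = np.linspace(-0.2, 10.0, 150)
    analytic = pk.concentration_profiles(s, irf, delays)
    assert np.all(np.isfinite(analytic))
    numeric = _ode_oracle(s, irf, delays)
    # 1e-6 relative rate perturbation instead of a t*exp(-kt) basis
    assert np.max(np.abs(analytic - numeric)) < 1e-4


def test_irf_kernel_matches_quadrature():
    from scipy.integrate import quad

    irf = pk.InstrumentResponse(fwhm=120.0, t0=50.0)
    k, s, t0 = 1 / 0.7, irf.sigma_ps, irf.t0_ps
    tg = np.array([-0.4, -0.1, -0.02, 0.0, 0.05, 0.2, 0.5, 1.0, 3.0, 6.0])

    def oracle(t):
        pts = sorted(p for p in (t - t0 - 5 * s, t - t0, t - t0 + 5 * s)
                     if 0.0 < p < 50.0)
        val, _ = quad(
            lambda u: np.exp(-k * u)
            * np.exp(-((t - t0 - u) ** 2) / (2 * s * s))
            / (s * np.sqrt(2 * np.pi)),
            0.0, 50.0, limit=400, points=pts or None,
            epsabs=1e-13, epsrel=1e-12,
        )
        return val

    expected = np.array([oracle(t) for t in tg])
    assert np.allclose(irf_kernel(tg, k, irf), expected, atol=1e-9)


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


def test_varpro_equals_per_pixel_ols(make_vis_dataset, irf):
    ds = make_vis_dataset(sigma=0.05, seed=4)
    taus = np.array([0.05, 0.15, 1.5, 4.0])
    X, C, _ = _varpro_solve(taus, ds.delays, ds.values, irf, True)
    for j in [0, 17, 41, 79]:
        beta, *_ = np.linalg.lstsq(X, ds.values[:, j], rcond=None)
        assert np.allclose(C[:, j], beta, atol=1e-10)


def test_global_fit_recovery_noiseless(irf):
    # three parallel compartments = plain 3-exponential decay
    s = pk.CompartmentScheme(
        ["A", "B", "C", "sink"], {"A": 0.2, "B": 1.1, "C": 5.0},
        {"A": {"sink": 1.0}, "B": {"sink": 1.0}, "C": {"sink": 1.0}},
        {"A": 0.4, "B": 0.3, "C": 0.3}, ground_state="sink",
    )
    wn = np.linspace(10000, 13000, 30)
    bands = [
        pk.SpectralBand("a", 10500, 600, 3.0, compartment="A"),
        pk.SpectralBand("b", 11500, 600, -2.0, compartment="B"),
        pk.SpectralBand("c", 12500, 600, 1.5, compartment="C"),
    ]
    ds = pk.simulate_ta(s, bands, pk.default_delays(t_max=25), wn, irf)
    res = pk.global_fit(ds, 3, init=[0.4, 2.0, 9.0], irf=irf)
    assert np.max(np.abs(res.time_constants - [0.2, 1.1, 5.0])
                  / np.array([0.2, 1.1, 5.0])) < 1e-4


def test_global_fit_idempotent(make_vis_dataset, irf):
    ds = make_vis_dataset(sigma=0.08, seed=9)
    first = pk.global_fit(ds, 4, init=[0.1, 0.3, 3.0, 8.0], irf=irf)
    recon = pk.TADataset(ds.delays, ds.wavenumbers, first.model)
    second = pk.global_fit(recon, 4, init=list(first.time_constants), irf=irf)
    rel = np.abs(second.time_constants - first.time_constants) / first.time_constants
    assert np.max(rel) < 1e-8


def test_model_plus_residuals_reconstructs_data(make_vis_dataset, irf):
    ds = make_vis_dataset(sigma=0.08, seed=5)
    res = pk.global_fit(ds, 4, init=[0.1, 0.3, 3.0, 8.0], irf=irf)
    assert np.allclose(res.model + res.residuals, ds.values, atol=1e-9)
    assert res.das.shape[0] == 4


def test_pure_noise_flagged_insignificant(vis_grid, irf):
    delays, wn = vis_grid
    rng = np.random.default_rng(11)
    ds = pk.TADataset(delays, wn, rng.normal(0, 0.05, (delays.size, wn.size)))
    res = pk.global_fit(ds, 2, init=[0.3, 3.0], irf=irf)
    assert not np.any(res.significant)
    assert "no significant component" in res.message


def test_irf_limited_component_flagged(make_vis_dataset, irf):
    ds = make_vis_dataset(sigma=0.08, seed=3)
    res = pk.global_fit(ds, 4, init=[0.1, 0.3, 3.0, 8.0], irf=irf)
    assert res.irf_limited[0]          # ~50 fs < 60 fs IRF FWHM
    assert not res.irf_limited[1:].any()
    # IRF-limited uncertainty reported as at least +/- tau itself
    assert res.tau_errors[0] >= res.time_constants[0]


# ---------------------------------------------------------------------------
# Target analysis
# ---------------------------------------------------------------------------


def test_sas_equals_das_for_parallel_scheme(irf):
    s = pk.CompartmentScheme(
        ["A", "B", "sinkA", "sinkB"], {"A": 0.5, "B": 3.0},
        {"A": {"sinkA": 1.0}, "B": {"sinkB": 1.0}},
        {"A": 0.6, "B": 0.4},
    )
    wn = np.linspace(10000, 12000, 20)
    bands = [pk.SpectralBand("a", 10500, 500, 2.0, compartment="A"),
             pk.SpectralBand("b", 11500, 500, -1.0, compartment="B")]
    ds = pk.simulate_ta(s, bands, pk.default_delays(t_max=20), wn, irf)
    res = pk.global_fit(ds, 2, init=[0.5, 3.0], irf=irf, include_const=True)
    sas = pk.das_to_sas(res, s, zero_states=["sinkA", "sinkB"])
    # non-interconverting compartments: SAS rows = DAS rows (A is diagonal
    # in initial populations), up to the per-state excitation weight
    assert np.allclose(sas[0] * 0.6, res.das[0], atol=1e-8)
    assert np.allclose(sas[1] * 0.4, res.das[1], atol=1e-8)


def test_sas_round_trip_sequential_scheme(irf):
    s = pk.CompartmentScheme(
        ["A", "B", "G"], {"A": 0.3, "B": 2.0},
        {"A": {"B": 1.0}, "B": {"G": 1.0}}, {"A": 1.0}, ground_state="G",
    )
    wn = np.linspace(10000, 12000, 25)
    bands = [pk.SpectralBand("a", 10500, 400, 2.0, compartment="A"),
             pk.SpectralBand("b", 11400, 400, 1.0, compartment="B"),
             pk.SpectralBand("gsb", 11000, 600, -1.5, compartment=pk.BLEACH)]
    ds = pk.simulate_ta(s, bands, pk.default_delays(t_max=20), wn, irf)
    res = pk.global_fit(ds, 2, init=[0.3, 2.0], irf=irf)
    sas = pk.das_to_sas(res, s)
    from photokin.simulate import band_matrix
    bleach = band_matrix([bands[2]], wn)[0]
    truthA = band_matrix([bands[0]], wn)[0] + bleach
    truthB = band_matrix([bands[1]], wn)[0] + bleach
    peak = np.abs(ds.values).max()
    assert np.max(np.abs(sas[0] - truthA)) < 1e-6 * peak
    assert np.max(np.abs(sas[1] - truthB)) < 1e-6 * peak


def test_sas_round_trip_default_scheme(scheme, irf, make_vis_dataset):
    ds = make_vis_dataset()
    res = pk.global_fit(ds, 4, init=[0.05, 0.15, 1.5, 4.0], irf=irf)
    sas = pk.das_to_sas(res, scheme)
    from photokin.simulate import band_matrix
    bands = pk.default_bands_vis()
    wn = ds.wavenumbers
    bleach = band_matrix([b for b in bands if b.compartment == pk.BLEACH], wn).sum(axis=0)
    peak = np.abs(ds.values).max()
    for i, st in enumerate(res.sas_states):
        own = [b for b in bands if b.compartment == st]
        truth = (band_matrix(own, wn).sum(axis=0) if own else np.zeros_like(wn)) + bleach
        assert np.max(np.abs(sas[i] - truth)) < 1e-6 * peak
    # reconstruction through scheme populations reproduces the fitted model
    C = pk.concentration_profiles(scheme, res.irf, ds.delays)
    keep = [scheme.states.index(s) for s in res.sas_states]
    recon = C[keep].T @ sas
    assert np.max(np.abs(recon - res.model)) < 1e-9 * peak


def test_sas_component_count_mismatch_reported(scheme, irf, make_vis_dataset):
    ds = make_vis_dataset()
    res = pk.global_fit(ds, 2, init=[0.1, 2.0], irf=irf)
    with pytest.raises(ValueError, match="eigenrates"):
        pk.das_to_sas(res, scheme)
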