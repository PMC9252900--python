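"""Compartment kinetics, variable-projection global fitting and target analysis.

The photocycle is modelled as a directed acyclic graph of compartments with
first-order decay. Lifetimes are in ps; branching fractions out of every
non-terminal state sum to one. The analytic solution is a sum of exponentials,
each convolved with a Gaussian instrument response via the closed-form
exponentially-modified-Gaussian kernel

    g(t; k) = 1/2 * exp(k*(k*sigma^2/2 - (t - t0))) * (1 + erf((t - t0 - k*sigma^2)/(sigma*sqrt(2))))

evaluated in a numerically stable erfcx form.

Global lifetime analysis uses variable projection: the per-wavenumber linear
amplitudes (decay-associated difference spectra, DAS) are eliminated by exact
linear least squares inside every evaluation of the nonlinear cost, so only
the time constants (and optionally t0 / IRF width) are iterated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import numpy as np
from scipy.linalg import eig
from scipy.optimize import least_squares
from scipy.special import erfcx, wofz

__all__ = [
    "InstrumentResponse",
    "CompartmentScheme",
    "GlobalFitResult",
    "concentration_profiles",
    "global_fit",
    "das_to_sas",
    "overall_quantum_yield",
    "irf_kernel",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class InstrumentResponse:
    """Gaussian instrument response: ``fwhm`` and time-zero ``t0``, both in fs."""

    fwhm: float
    t0: float = 0.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("IRF fwhm must be > 0")

    @property
    def sigma(self) -> float:
        """Gaussian sigma in fs."""
        return self.fwhm * _FWHM_TO_SIGMA

    @property
    def sigma_ps(self) -> float:
        return self.sigma * 1e-3

    @property
    def t0_ps(self) -> float:
        return self.t0 * 1e-3


def irf_kernel(t_ps: np.ndarray, rate_per_ps: float, irf: InstrumentResponse | None) -> np.ndarray:
    """Exponential decay exp(-k t) Theta(t) convolved with a Gaussian IRF.

    ``rate_per_ps`` may be 0, giving the IRF-broadened step (terminal sinks).
    Without an IRF the sharp-onset exponential is returned.
    """
    t = np.asarray(t_ps, dtype=float)
    k = float(rate_per_ps)
    if irf is None or irf.fwhm == 0:
        dt = t
        out = np.where(dt >= 0, np.exp(-k * np.clip(dt, 0, None)), 0.0)
        return out
    s = irf.sigma_ps
    dt = t - irf.t0_ps
    z = (k * s * s - dt) / (s * np.sqrt(2.0))
    # erfcx form: g = 1/2 exp(-dt^2/(2 s^2)) erfcx(z); for strongly negative z
    # (late times) erfcx overflows, so switch to the plain product there.
    with np.errstate(over="ignore", under="ignore"):
        safe = z > -6.0
        out = np.empty_like(dt)
        out[safe] = 0.5 * np.exp(-dt[safe] ** 2 / (2 * s * s)) * erfcx(z[safe])
        out[~safe] = np.exp(k * (k * s * s / 2.0 - dt[~safe]))
    return out


def irf_kernel_complex(t_ps: np.ndarray, kappa, irf: InstrumentResponse | None) -> np.ndarray:
    """Gaussian-IRF convolution of exp(-kappa t) Theta(t) for complex kappa.

    With kappa = 1/tau - i*omega the real part of exp(i*phi) times this
    kernel is the IRF-convolved damped cosine. Uses erfcx(z) = wofz(i z).
    """
    t = np.asarray(t_ps, dtype=float)
    k = complex(kappa)
    if irf is None or irf.fwhm == 0:
        return np.where(t >= 0, np.exp(-k * np.clip(t, 0, None)), 0.0)
    s = irf.sigma_ps
    dt = t - irf.t0_ps
    z = (k * s * s - dt) / (s * np.sqrt(2.0))
    out = np.empty(t.shape, dtype=complex)
    safe = z.real > -6.0
    out[safe] = 0.5 * np.exp(-dt[safe] ** 2 / (2 * s * s)) * wofz(1j * z[safe])
    out[~safe] = np.exp(k * (k * s * s / 2.0 - dt[~safe]))
    return out


# ---------------------------------------------------------------------------
# Scheme
# ---------------------------------------------------------------------------


@dataclass
class CompartmentScheme:
    """Directed acyclic kinetic scheme of photocycle compartments.

    ``lifetimes`` maps non-terminal states to 1/e lifetimes in ps; states
    absent from it are terminal sinks. ``branching[src][dst]`` are outgoing
    fractions that must sum to 1 per source. ``ground_state`` names the
    recovered electronic ground state, which carries no difference-absorbance
    signal (used for the bleach profile and for target analysis).
    """

    states: list
    lifetimes: dict
    branching: dict
    initial_population: dict
    ground_state: str | None = None

    def __post_init__(self):
        self.states = list(self.states)
        self.validate()

    def validate(self):
        index = {s: i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise ValueError("duplicate state labels")
        for s, tau in self.lifetimes.items():
            if s not in index:
                raise ValueError(f"unknown state in lifetimes: {s!r}")
            if not tau > 0:
                raise ValueError(f"lifetime of {s!r} must be > 0")
        for src, out in self.branching.items():
            if src not in self.lifetimes:
                raise ValueError(f"branching from terminal or unknown state {src!r}")
            tot = sum(out.values())
            if not np.isclose(tot, 1.0, atol=1e-9):
                raise ValueError(f"branching out of {src!r} sums to {tot}, not 1")
            for dst, frac in out.items():
                if dst not in index:
                    raise ValueError(f"unknown branching target {dst!r}")
                if frac < 0:
                    raise ValueError("negative branching fraction")
        for s in self.lifetimes:
            if s not in self.branching:
                raise ValueError(f"non-terminal state {s!r} has no branching targets")
        p0 = sum(self.initial_population.values())
        if not np.isclose(p0, 1.0, atol=1e-9):
            raise ValueError(f"initial population sums to {p0}, not 1")
        for s in self.initial_population:
            if s not in index:
                raise ValueError(f"unknown state in initial_population: {s!r}")
        if self.ground_state is not None and self.ground_state not in index:
            raise ValueError(f"unknown ground_state {self.ground_state!r}")
        # acyclicity
        ts = TopologicalSorter({s: set() for s in self.states})
        for src, out in self.branching.items():
            for dst in out:
                ts.add(dst, src)
        try:
            list(ts.static_order())
        except Exception as exc:  # CycleError
            raise ValueError(f"kinetic scheme contains a cycle: {exc}") from exc

    # -- derived structure -------------------------------------------------
    @property
    def terminal_states(self) -> list:
        return [s for s in self.states if s not in self.lifetimes]

    def rate_matrix(self, degenerate_eps: float = 1e-6) -> np.ndarray:
        """First-order rate matrix K with dc/dt = K c.

        Coinciding decay rates (within 1e-9 relative) are perturbed by
        ``degenerate_eps`` relative so the matrix stays diagonalizable with a
        pure exponential basis.
        """
        rates = {}
        seen = []
        for s in self.states:
            tau = self.lifetimes.get(s)
            if tau is None:
                rates[s] = 0.0
                continue
            k = 1.0 / tau
            while any(abs(k - k0) <= 1e-9 * max(k, k0) for k0 in seen):
                k *= 1.0 + degenerate_eps
            seen.append(k)
            rates[s] = k
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        K = np.zeros((n, n))
        for s in self.states:
            K[idx[s], idx[s]] = -rates[s]
        for src, out in self.branching.items():
            for dst, frac in out.items():
                K[idx[dst], idx[src]] += frac * rates[src]
        return K

    def exponential_modes(self):
        """Analytic solution c_i(t) = sum_m A[i, m] exp(-kappa_m t).

        Returns ``(kappas, A)`` with distinct decay rates ``kappas`` (1/ps,
        zero included when terminal sinks exist) and the state x mode
        amplitude matrix ``A``; modes sharing a rate are merged.
        """
        K = self.rate_matrix()
        c0 = np.array([self.initial_population.get(s, 0.0) for s in self.states])
        lam, V = eig(K)
        lam = lam.real
        coef = np.linalg.solve(V, c0.astype(complex)).real
        A_full = V.real * coef[np.newaxis, :]
        kappas_full = -lam
        # merge numerically identical rates (e.g. several terminal sinks at 0)
        order = np.argsort(kappas_full)
        kappas, cols = [], []
        for m in order:
            k = kappas_full[m]
            if kappas and abs(k - kappas[-1]) <= 1e-9 * max(abs(k), abs(kappas[-1]), 1e-12):
                cols[-1] = cols[-1] + A_full[:, m]
            else:
                kappas.append(k)
                cols.append(A_full[:, m].copy())
        return np.array(kappas), np.column_stack(cols)


def concentration_profiles(
    scheme: CompartmentScheme,
    irf: InstrumentResponse | None,
    delays_ps: np.ndarray,
) -> np.ndarray:
    """Analytic IRF-convolved populations, shape (n_states, n_delays)."""
    delays_ps = np.asarray(delays_ps, dtype=float)
    kappas, A = scheme.exponential_modes()
    basis = np.stack([irf_kernel(delays_ps, k, irf) for k in kappas])  # modes x t
    C = A @ basis
    np.clip(C, -1e-12, None, out=C)
    return C


# ---------------------------------------------------------------------------
# Quantum yield
# ---------------------------------------------------------------------------


def overall_quantum_yield(scheme: CompartmentScheme, product: str) -> float:
    """Fraction of the excited population ending in ``product``.

    Sum over all directed paths from the initially populated states to the
    (terminal) product of the product of branching fractions along each path.
    """
    if product not in scheme.states:
        raise ValueError(f"unknown state label {product!r}")
    memo: dict = {}

    def reach(s):
        if s == product:
            return 1.0
        if s not in scheme.branching:
            return 0.0
        if s not in memo:
            memo[s] = sum(frac * reach(dst) for dst, frac in scheme.branching[s].items())
        return memo[s]

    return float(sum(p * reach(s) for s, p in scheme.initial_population.items()))


# ---------------------------------------------------------------------------
# Variable-projection global fit
# ---------------------------------------------------------------------------


@dataclass
class GlobalFitResult:
    """Result of a variable-projection global lifetime fit.

    ``das`` rows are the decay-associated difference spectra of the fitted
    exponentials (sorted by increasing time constant); the optional
    non-decaying component's spectrum is in ``offset_spectrum``.
    """

    time_constants: np.ndarray          # ps, ascending
    tau_errors: np.ndarray              # ps, 1-sigma from local curvature
    irf: InstrumentResponse
    das: np.ndarray                     # n_exp x n_wn, mOD
    offset_spectrum: np.ndarray | None  # n_wn, mOD (infinite-time component)
    residuals: np.ndarray               # n_t x n_wn (full data grid)
    cost: float                         # sum of squared fitted residuals
    delays: np.ndarray
    wavenumbers: np.ndarray
    irf_limited: np.ndarray             # bool per component: tau < IRF fwhm
    significant: np.ndarray             # bool per component: max|DAS| > 3 sigma_res
    fitted_mask: np.ndarray             # delays actually entering the cost
    sas: np.ndarray | None = None       # states x n_wn after target analysis
    sas_states: list | None = None
    n_restarts: int = 1
    converged: bool = True
    message: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def model(self) -> np.ndarray:
        """Fitted reconstruction on the full data grid (data = model + residuals)."""
        X = _design_matrix(self.time_constants, self.delays, self.irf,
                           self.offset_spectrum is not None)
        C = self.das if self.offset_spectrum is None else np.vstack(
            [self.das, self.offset_spectrum])
        return X @ C


def _design_matrix(taus, delays_ps, irf, include_const: bool) -> np.ndarray:
    cols = [irf_kernel(delays_ps, 1.0 / tau, irf) for tau in taus]
    if include_const:
        cols.append(irf_kernel(delays_ps, 0.0, irf))
    return np.column_stack(cols)


def _varpro_solve(taus, delays, data, irf, include_const):
    """Exact linear LS amplitudes for fixed nonlinear parameters."""
    X = _design_matrix(taus, delays, irf, include_const)
    C, *_ = np.linalg.lstsq(X, data, rcond=None)
    R = data - X @ C
    return X, C, R


def _ladder_guesses(t_grid, n_exp, n_restarts=8):
    """Deterministic log-spaced initial-guess ladders over the delay span."""
    t_pos = t_grid[t_grid > 0]
    lo = max(t_pos.min() if t_pos.size else 1e-3, 1e-3)
    hi = max(t_grid.max(), lo * 10)
    ladders = []
    for j in range(n_restarts):
        shift = 10 ** (0.25 * (j - (n_restarts - 1) / 2))
        ladders.append(np.geomspace(lo * shift, hi * shift, n_exp))
    return ladders


def global_fit(
    data,
    n_exponentials: int,
    init=None,
    fit_irf: bool = False,
    irf: InstrumentResponse | None = None,
    include_const: bool = True,
    exclude_pre_t0: bool = True,
    weights=None,
) -> GlobalFitResult:
    """Global multiexponential lifetime analysis of a TA dataset.

    Parameters
    ----------
    data:
        :class:`~photokin.dataset.TADataset`.
    n_exponentials:
        Number of decaying components. With ``include_const`` an additional
        non-decaying (IRF-broadened step) component absorbs long-lived
        photoproduct signal.
    init:
        Initial time constants (ps). When omitted, a deterministic ladder of
        8 log-spaced restarts over the delay span is tried and the best kept.
    fit_irf:
        Also optimize t0 and the IRF width.
    irf:
        Fixed (or initial, with ``fit_irf``) instrument response. Defaults to
        60 fs FWHM at t0 = 0.
    exclude_pre_t0:
        Drop delays earlier than t0 - 5 sigma_IRF from the cost (signals
        there, e.g. perturbed free-induction decay, are outside the model).
    weights:
        Optional per-wavenumber sigma; residuals are divided by it.
    """
    if n_exponentials < 1:
        raise ValueError("n_exponentials must be >= 1")
    delays, wavenumbers, D = data.delays, data.wavenumbers, data.values
    if irf is None:
        irf = InstrumentResponse(fwhm=60.0, t0=0.0)

    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != wavenumbers.shape:
            raise ValueError("weights must be per-wavenumber")

    def make_mask(t0_ps, sigma_ps):
        if not exclude_pre_t0:
            return np.ones_like(delays, dtype=bool)
        return delays >= t0_ps - 5.0 * sigma_ps

    def unpack(x):
        taus = np.exp(x[:n_exponentials])
        if fit_irf:
            cur_irf = InstrumentResponse(fwhm=abs(x[n_exponentials]) + 1e-3,
                                         t0=x[n_exponentials + 1])
        else:
            cur_irf = irf
        return taus, cur_irf

    def residual_vec(x):
        taus, cur_irf = unpack(x)
        mask = make_mask(cur_irf.t0_ps, cur_irf.sigma_ps)
        _, _, R = _varpro_solve(taus, delays[mask], D[mask], cur_irf, include_const)
        if w is not None:
            R = R / w
        return R.ravel()

    if init is not None:
        init_list = [np.asarray(init, dtype=float)]
        if len(init_list[0]) != n_exponentials:
            raise ValueError("init length must equal n_exponentials")
    else:
        init_list = _ladder_guesses(delays, n_exponentials)

    best = None
    for guess in init_list:
        x0 = np.log(np.asarray(guess, dtype=float))
        if fit_irf:
            x0 = np.concatenate([x0, [irf.fwhm, irf.t0]])
        try:
            sol = least_squares(residual_vec, x0, method="trf", x_scale="jac")
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("global fit failed for every initial guess")

    taus, fit_irf_obj = unpack(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    mask = make_mask(fit_irf_obj.t0_ps, fit_irf_obj.sigma_ps)
    X, C, Rfit = _varpro_solve(taus, delays[mask], D[mask], fit_irf_obj, include_const)
    das = C[:n_exponentials]
    offset = C[n_exponentials] if include_const else None

    # full-grid residual so that model + residuals == data exactly
    Xfull = _design_matrix(taus, delays, fit_irf_obj, include_const)
    residuals = D - Xfull @ C

    cost = float(np.sum(Rfit**2))
    dof = max(Rfit.size - best.x.size - C.size, 1)
    sigma2 = cost / dof
    # curvature of the varpro cost in the nonlinear parameters
    J = best.jac
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
        tau_errors = (np.exp(best.x[:n_exponentials]) * perr[:n_exponentials])[order]
    except np.linalg.LinAlgError:
        tau_errors = np.full(n_exponentials, np.nan)

    sigma_res = float(np.std(Rfit))
    irf_limited = taus < fit_irf_obj.fwhm * 1e-3
    # per-component significance: largest amplitude/uncertainty ratio across
    # pixels, with sigma_amp from the varpro linear problem
    XtX_inv = np.linalg.pinv(X.T @ X)
    amp_sigma = sigma_res * np.sqrt(np.clip(np.diag(XtX_inv)[:n_exponentials], 0, None))
    with np.errstate(divide="ignore"):
        tstat = np.max(np.abs(das), axis=1) / np.where(amp_sigma > 0, amp_sigma, np.inf)
    significant = tstat > 5.0
    # IRF-limited components: the data constrain tau no better than +/- tau
    tau_errors = np.where(irf_limited, np.maximum(tau_errors, taus), tau_errors)

    rates = 1.0 / taus
    dup = any(
        abs(rates[i] - rates[j]) <= 1e-9 * max(rates[i], rates[j])
        for i, j in itertools.combinations(range(len(rates)), 2)
    )
    message = best.message
    if dup:
        message += " [rank-deficient: duplicate time constants]"
    if not np.any(significant):
        message += " [no significant component: amplitudes below 3x residual noise]"

    return GlobalFitResult(
        time_constants=taus,
        tau_errors=tau_errors,
        irf=fit_irf_obj,
        das=das,
        offset_spectrum=offset,
        residuals=residuals,
        cost=cost,
        delays=delays,
        wavenumbers=wavenumbers,
        irf_limited=irf_limited,
        significant=significant,
        fitted_mask=mask,
        n_restarts=len(init_list),
        converged=bool(best.success and not dup),
        message=message.strip(),
    )


# ---------------------------------------------------------------------------
# Target analysis
# ---------------------------------------------------------------------------


def das_to_sas(fit: GlobalFitResult, scheme: CompartmentScheme,
               zero_states=None) -> np.ndarray:
    """Transform decay-associated into species-associated difference spectra.

    The scheme's analytic solution writes populations as ``P = A @ E`` with
    ``E`` the exponential basis; matching fitted components to scheme
    eigenrates gives ``DAS = A^T SAS``, solved for SAS. States listed in
    ``zero_states`` (default: the scheme's recovered ground state) are
    constrained to zero difference signal, which also removes the sink
    degeneracy of schemes with several terminal states.

    Returns the states x wavenumbers SAS matrix (and stores it on ``fit``
    together with the state labels).
    """
    kappas, A = scheme.exponential_modes()
    fitted_rates = list(1.0 / fit.time_constants)
    if fit.offset_spectrum is not None:
        fitted_rates.append(0.0)
        C = np.vstack([fit.das, fit.offset_spectrum])
    else:
        C = fit.das.copy()
    # sort both sides by rate
    korder = np.argsort(kappas)
    forder = np.argsort(fitted_rates)
    kappas = np.asarray(kappas)[korder]
    A = A[:, korder]
    fitted_rates = [fitted_rates[i] for i in forder]
    C = C[forder]

    if zero_states is None:
        zero_states = [scheme.ground_state] if scheme.ground_state else []
    keep = [i for i, s in enumerate(scheme.states) if s not in set(zero_states)]
    labels = [scheme.states[i] for i in keep]
    Ak = A[keep]

    # drop modes that carry no amplitude in any observed state (e.g. the
    # rate-0 mode of a scheme whose only sink is the recovered ground state)
    observable = np.max(np.abs(Ak), axis=0) > 1e-12
    for m in np.nonzero(~observable)[0]:
        if fitted_rates:
            j = int(np.argmin(np.abs(np.asarray(fitted_rates) - kappas[m])))
            fitted_rates.pop(j)
            C = np.delete(C, j, axis=0)
    Ak = Ak[:, observable]
    kappas = kappas[observable]

    if len(fitted_rates) != len(kappas):
        raise ValueError(
            f"scheme has {len(kappas)} observable eigenrates but the fit has "
            f"{len(fitted_rates)} exponential components"
        )
    if Ak.shape[0] != Ak.shape[1]:
        raise ValueError(
            f"amplitude matrix is {Ak.shape[0]} states x {Ak.shape[1]} modes; "
            "constrain more states to zero or adjust the scheme"
        )
    condition = np.linalg.cond(Ak)
    if condition > 1e12:
        raise ValueError(
            f"amplitude matrix is singular (cond={condition:.2e}): a state is "
            "unobservable under this branching"
        )
    sas = np.linalg.solve(Ak.T, C)
    fit.sas = sas
    fit.sas_states = labels
    return sas
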