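"""Synthetic polarization-resolved transient-absorption data.

Forward simulator of the branching Pfr photocycle of the bathyphytochrome
Agp2: on excitation the S1 population relaxes and bifurcates 1:1 within
~50 fs into a protonated and a (chromophore-)deprotonated excited-state
branch; the protonated branch crosses to a vibrationally hot ground state
GS* with 150 fs; the deprotonated branch decays with 1.5 ps to the early
Lumi-F photoproduct (ELF, 70%) and to GS* (30%); GS* cools back to the Pfr
ground state with 4 ps. The overall ELF quantum yield of the default scheme
is therefore 0.5 x 0.7 = 0.35.

Every generated dataset is a deterministic function of its parameters and
seed, so downstream inference (global fitting, anisotropy, oscillation and
band analysis) can be tested without any measured data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .dataset import TADataset
from .kinetics import CompartmentScheme, InstrumentResponse, concentration_profiles

__all__ = [
    "BLEACH",
    "MAGIC_ANGLE_DEG",
    "C_CM_PER_FS",
    "BandShape",
    "SpectralBand",
    "NoiseSpec",
    "TitrationSeries",
    "OscillationComponent",
    "default_scheme_pfr",
    "default_bands_vis",
    "default_bands_ir",
    "default_oscillations",
    "band_matrix",
    "anisotropy_from_angle",
    "simulate_ta",
    "simulate_titration",
    "simulate_bleach_pair",
    "langevin_dipole_trajectory",
]

#: pseudo-compartment label whose population is the depleted ground state
#: (1 - recovered S0), i.e. the sum of all transient populations.
BLEACH = "bleach"

#: pump/probe angle at which single-transition dichroism vanishes.
MAGIC_ANGLE_DEG = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))

#: speed of light, cm per fs (converts cm^-1 to cycles/fs).
C_CM_PER_FS = 2.99792e-5


class BandShape(str, enum.Enum):
    gaussian = "gaussian"
    lorentzian = "lorentzian"
    flat_plateau = "flat_plateau"


@dataclass
class SpectralBand:
    """One spectral feature attached to a kinetic compartment.

    ``amplitude`` is the signed peak difference absorbance in mOD (negative
    for bleach / stimulated emission). ``tdm_angle`` is the angle in degrees
    between this band's transition dipole moment and the pumped electronic
    TDM; ``None`` means the magic angle (no dichroism). ``flat_plateau``
    bands need explicit ``low``/``high`` edges (cm^-1) and use soft
    error-function edges of width ``edge_width``.
    """

    label: str
    center: float
    fwhm: float
    amplitude: float
    shape: BandShape = BandShape.gaussian
    tdm_angle: float | None = None
    compartment: str = "S1"
    low: float | None = None
    high: float | None = None
    edge_width: float = 10.0

    def __post_init__(self):
        self.shape = BandShape(self.shape)
        if self.shape is not BandShape.flat_plateau and not self.fwhm > 0:
            raise ValueError(f"band {self.label!r}: fwhm must be > 0")
        if self.shape is BandShape.flat_plateau and (self.low is None or self.high is None):
            raise ValueError(f"flat_plateau band {self.label!r} needs low/high edges")
        if self.tdm_angle is not None and not (0.0 <= self.tdm_angle <= 90.0):
            raise ValueError(f"band {self.label!r}: tdm_angle must be in [0, 90] deg")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-peak line shape on the given wavenumber grid."""
        wn = np.asarray(wavenumbers, dtype=float)
        if self.shape is BandShape.gaussian:
            return np.exp(-4.0 * np.log(2.0) * ((wn - self.center) / self.fwhm) ** 2)
        if self.shape is BandShape.lorentzian:
            return 1.0 / (1.0 + (2.0 * (wn - self.center) / self.fwhm) ** 2)
        w = self.edge_width
        return 0.5 * (erf((wn - self.low) / w) - erf((wn - self.high) / w))

    @property
    def anisotropy(self) -> float:
        """Single-transition anisotropy r = 0.2 (3 cos^2 theta - 1)."""
        if self.tdm_angle is None:
            return 0.0
        return anisotropy_from_angle(self.tdm_angle)


def anisotropy_from_angle(theta_deg) -> float:
    return 0.2 * (3.0 * np.cos(np.radians(theta_deg)) ** 2 - 1.0)


@dataclass
class NoiseSpec:
    """Additive white Gaussian noise: per-point sigma in mOD plus a seed."""

    sigma_abs: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_abs < 0:
            raise ValueError("sigma_abs must be >= 0")


@dataclass
class TitrationSeries:
    """Transient-absorption amplitude (fixed delay/position) versus pH."""

    ph_values: np.ndarray
    amplitudes: np.ndarray
    errors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.ph_values.size != self.amplitudes.size:
            raise ValueError("ph_values and amplitudes lengths differ")
        if np.any(np.diff(self.ph_values) <= 0):
            raise ValueError("ph_values must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.size != self.ph_values.size:
                raise ValueError("errors length mismatch")


@dataclass
class OscillationComponent:
    """Damped coherent oscillation: A exp(-t/tau) cos(2 pi c nu t + phi)."""

    frequency: float       # cm^-1
    damping_time: float    # fs
    phase: float = 0.0     # rad
    amplitude: float = 1.0  # mOD

    def __post_init__(self):
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if not self.damping_time > 0:
            raise ValueError("damping_time must be > 0")

    def evaluate(self, t_ps: np.ndarray) -> np.ndarray:
        """Time course on a delay grid in ps (zero before t = 0)."""
        t_fs = np.asarray(t_ps, dtype=float) * 1e3
        y = (self.amplitude * np.exp(-np.clip(t_fs, 0, None) / self.damping_time)
             * np.cos(2.0 * np.pi * C_CM_PER_FS * self.frequency * t_fs + self.phase))
        return np.where(t_fs >= 0, y, 0.0)


# ---------------------------------------------------------------------------
# Defaults: the Agp2 Pfr photoreaction
# ---------------------------------------------------------------------------


def default_scheme_pfr() -> CompartmentScheme:
    """Six-state branching scheme of the Pfr photoreaction.

    S1 -(50 fs, 1:1)-> {ES_prot, ES_deprot}; ES_prot -(150 fs)-> GS*;
    ES_deprot -(1.5 ps)-> {ELF: 0.7, GS*: 0.3}; GS* -(4 ps)-> S0 (Pfr).
    ELF and S0 are terminal within the simulated window; S0 is the recovered
    ground state (zero difference signal).
    """
    return CompartmentScheme(
        states=["S1", "ES_prot", "ES_deprot", "GS*", "ELF", "S0"],
        lifetimes={"S1": 0.050, "ES_prot": 0.150, "ES_deprot": 1.5, "GS*": 4.0},
        branching={
            "S1": {"ES_prot": 0.5, "ES_deprot": 0.5},
            "ES_prot": {"GS*": 1.0},
            "ES_deprot": {"ELF": 0.7, "GS*": 0.3},
            "GS*": {"S0": 1.0},
        },
        initial_population={"S1": 1.0},
        ground_state="S0",
    )


def default_bands_vis() -> list:
    """Plausible VIS band table for the Pfr photoreaction simulator.

    Centers follow the reported signatures (bleach of the Pfr absorption,
    SE1 ~12,900 cm^-1, redshifted SE2 ~11,000 cm^-1, ESA ~14,700 cm^-1, hot
    ground-state absorption GS* at 12,435 cm^-1); widths and amplitudes are
    free generator parameters chosen to look like the measured spectra.
    """
    return [
        SpectralBand("GSB", 13100.0, 900.0, -8.0, compartment=BLEACH, tdm_angle=0.0),
        SpectralBand("SE1", 12900.0, 1100.0, -6.0, compartment="S1", tdm_angle=0.0),
        SpectralBand("ESA", 14700.0, 1500.0, 5.0, compartment="S1", tdm_angle=20.0),
        SpectralBand("SE1'", 12800.0, 1100.0, -4.0, compartment="ES_prot", tdm_angle=0.0),
        SpectralBand("ESA'", 14700.0, 1500.0, 4.0, compartment="ES_prot", tdm_angle=20.0),
        SpectralBand("SE2", 11000.0, 1300.0, -5.0, compartment="ES_deprot", tdm_angle=10.0),
        SpectralBand("ESA''", 14500.0, 1600.0, 3.0, compartment="ES_deprot", tdm_angle=20.0),
        SpectralBand("GS*", 12435.0, 1000.0, 4.0, compartment="GS*", tdm_angle=5.0),
        SpectralBand("ELF", 12700.0, 900.0, 2.5, compartment="ELF", tdm_angle=15.0),
    ]


def default_bands_ir() -> list:
    """IR fingerprint/continuum band table (D2O difference-spectrum region).

    Ring-D carbonyl bleach at 1,684 cm^-1, its excited-state band at
    1,666 cm^-1 and the ELF product band at 1,692 cm^-1; propionic side
    chain C carbonyl bleach 1,743 / excited-state 1,727 / product
    1,735 cm^-1; plus the broad continuum band (CB) of the proton-loaded
    water network as a flat plateau over 1,750-1,900 cm^-1 attached to the
    deprotonated excited-state branch, with a TDM angle of 34 deg to the
    electronic TDM.
    """
    return [
        SpectralBand("v(C=O)_D", 1684.0, 12.0, -5.0, compartment=BLEACH, tdm_angle=0.0),
        SpectralBand("v(C=O)_D*", 1666.0, 14.0, 3.5, compartment="ES_prot", tdm_angle=0.0),
        SpectralBand("v(C=O)_D* dep", 1666.0, 14.0, 3.5, compartment="ES_deprot", tdm_angle=0.0),
        SpectralBand("v(C=O)_DELF", 1692.0, 12.0, 1.7, compartment="ELF", tdm_angle=10.0),
        SpectralBand("propC_Pfr", 1743.0, 10.0, -3.0, compartment=BLEACH, tdm_angle=0.0),
        SpectralBand("propC*", 1727.0, 14.0, 2.0, compartment="ES_deprot", tdm_angle=0.0),
        SpectralBand("propC_ELF", 1735.0, 10.0, 1.05, compartment="ELF", tdm_angle=10.0),
        SpectralBand("CB", 1825.0, 150.0, 1.5, shape=BandShape.flat_plateau,
                     low=1750.0, high=1900.0, edge_width=15.0,
                     compartment="ES_deprot", tdm_angle=34.0),
    ]


def default_oscillations() -> list:
    """The dominant coherent doublet: 300 and 340 cm^-1, 160 fs damping."""
    return [
        OscillationComponent(300.0, 160.0, phase=0.0, amplitude=0.5),
        OscillationComponent(340.0, 160.0, phase=0.6, amplitude=0.4),
    ]


def default_delays(t_max: float = 15.0, n_early: int = 60, n_late: int = 60) -> np.ndarray:
    """Delay grid in ps: dense linear coverage of the IRF region followed by
    a log-spaced tail, plus a few pre-time-zero points."""
    early = np.linspace(-0.3, 1.0, n_early)
    late = np.geomspace(1.05, t_max, n_late)
    return np.concatenate([early, late])


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def band_matrix(bands, wavenumbers) -> np.ndarray:
    """Stack of signed band spectra, shape (n_bands, n_wn), in mOD."""
    wn = np.asarray(wavenumbers, dtype=float)
    return np.stack([b.amplitude * b.profile(wn) for b in bands])


def _compartment_profiles(scheme, irf, delays):
    """Populations per compartment plus the bleach pseudo-compartment."""
    C = concentration_profiles(scheme, irf, delays)
    profiles = {s: C[i] for i, s in enumerate(scheme.states)}
    if scheme.ground_state is not None:
        bleach = sum(C[i] for i, s in enumerate(scheme.states)
                     if s != scheme.ground_state)
    else:
        bleach = C.sum(axis=0)
    profiles[BLEACH] = bleach
    return profiles


def simulate_ta(
    scheme: CompartmentScheme,
    bands,
    delays,
    wavenumbers,
    irf: InstrumentResponse,
    noise: NoiseSpec | None = None,
    oscillations=(),
    channel: str = "iso",
    oscillation_envelope: str | None = "ES_prot",
):
    """Simulate a transient-absorption dataset from a kinetic scheme.

    The isotropic signal is ``dA(t, nu) = sum_bands c_comp(t) S_band(nu)``
    plus an oscillatory residual and noise. Polarized channels follow each
    band's TDM angle through ``r = 0.2 (3 cos^2 theta - 1)``:
    ``par = iso (1 + 2 r)``, ``per = iso (1 - r)``.

    Coherent oscillations switch on with the IRF-convolved excitation onset
    (their stated damping time is the observable damping of the residual)
    and carry the spectral profile of the ``oscillation_envelope``
    compartment's bands; they are magic-angle (isotropic) contributions.

    ``channel`` is one of ``iso``, ``par``, ``per`` or ``both``; ``both``
    returns ``{"par": ..., "per": ..., "iso": ...}`` with iso built from the
    noisy polarized channels as (par + 2 per)/3.
    """
    delays = np.asarray(delays, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    for name, ax in (("delays", delays), ("wavenumbers", wavenumbers)):
        if ax.size == 0 or (ax.size > 1 and not np.all(np.diff(ax) > 0)):
            raise ValueError(f"{name} grid must be non-empty and strictly increasing")
    if channel not in ("iso", "par", "per", "both"):
        raise ValueError(f"unknown channel {channel!r}")

    profiles = _compartment_profiles(scheme, irf, delays)
    for b in bands:
        if b.compartment not in profiles:
            raise ValueError(f"band {b.label!r}: unknown compartment {b.compartment!r}")

    n_t, n_w = delays.size, wavenumbers.size
    iso = np.zeros((n_t, n_w))
    par = np.zeros((n_t, n_w))
    per = np.zeros((n_t, n_w))
    for b in bands:
        contrib = np.outer(profiles[b.compartment], b.amplitude * b.profile(wavenumbers))
        r = b.anisotropy
        iso += contrib
        par += contrib * (1.0 + 2.0 * r)
        per += contrib * (1.0 - r)

    if oscillations:
        # analytic IRF convolution of each damped cosine (complex-rate EMG
        # kernel); spectral profile from the carrier compartment's bands
        from .kinetics import irf_kernel_complex

        if oscillation_envelope is not None and oscillation_envelope in profiles:
            spec_bands = [b for b in bands if b.compartment == oscillation_envelope]
        else:
            spec_bands = []
        if spec_bands:
            spec = np.abs(band_matrix(spec_bands, wavenumbers)).sum(axis=0)
            m = spec.max()
            spec = spec / m if m > 0 else np.ones(n_w)
        else:
            spec = np.ones(n_w)
        osc_t = np.zeros(n_t)
        for o in oscillations:
            kappa = 1e3 / o.damping_time - 1j * (
                2.0 * np.pi * C_CM_PER_FS * o.frequency * 1e3)  # per ps
            kern = irf_kernel_complex(delays, kappa, irf)
            osc_t += o.amplitude * np.real(np.exp(1j * o.phase) * kern)
        osc = np.outer(osc_t, spec)
        iso += osc
        par += osc
        per += osc

    rng = np.random.default_rng(noise.seed) if noise is not None else None

    def with_noise(values):
        if rng is None or noise.sigma_abs == 0:
            return values
        return values + rng.normal(0.0, noise.sigma_abs, size=values.shape)

    meta = {"scheme_states": list(scheme.states), "irf_fwhm_fs": irf.fwhm,
            "irf_t0_fs": irf.t0}
    if channel == "both":
        # draw par then per so the pair is deterministic in the seed
        par_ds = TADataset(delays, wavenumbers, with_noise(par), "par", dict(meta))
        per_ds = TADataset(delays, wavenumbers, with_noise(per), "per", dict(meta))
        iso_ds = TADataset(delays, wavenumbers,
                           (par_ds.values + 2.0 * per_ds.values) / 3.0, "iso", dict(meta))
        return {"par": par_ds, "per": per_ds, "iso": iso_ds}
    picked = {"iso": iso, "par": par, "per": per}[channel]
    return TADataset(delays, wavenumbers, with_noise(picked), channel, meta)


def simulate_titration(pka, a_low, a_high, ph_values, noise_sigma=0.0, seed=0,
                       errors=True) -> TitrationSeries:
    """Henderson-Hasselbalch amplitude titration with additive noise.

    amplitude(pH) = a_low + (a_high - a_low) / (1 + 10^(pKa - pH)).
    """
    ph = np.asarray(ph_values, dtype=float)
    if ph.size == 0:
        raise ValueError("ph_values must be non-empty")
    amp = a_low + (a_high - a_low) / (1.0 + 10.0 ** (pka - ph))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, noise_sigma, size=amp.shape)
    err = np.full(ph.shape, max(noise_sigma, 1e-12)) if errors else None
    return TitrationSeries(ph, amp, err, meta={"pka_true": pka, "seed": seed})


def simulate_bleach_pair(
    isomerization_fraction: float,
    wavenumbers=None,
    excited_fraction: float = 1.0,
    bleach_center: float = 1684.0,
    es_center: float = 1666.0,
    product_center: float = 1692.0,
    fwhm: float = 13.0,
    bleach_amplitude: float = -5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Early/late IR difference-spectrum pair for the bleach-ratio QY estimator.

    Early (during the excited state): full bleach plus the downshifted
    excited-state carbonyl band. Late (reaction completed): residual bleach
    scaled by the isomerization fraction plus the blueshifted photoproduct
    band. Returns ``(wavenumbers, early, late)``.
    """
    if wavenumbers is None:
        wavenumbers = np.arange(1630.0, 1721.0, 1.0)
    wn = np.asarray(wavenumbers, dtype=float)
    phi = float(isomerization_fraction)
    a0 = bleach_amplitude * excited_fraction
    early_bands = [
        SpectralBand("bleach", bleach_center, fwhm, a0, compartment=BLEACH),
        SpectralBand("ES", es_center, fwhm * 1.1, -0.7 * a0, compartment="S1"),
    ]
    late_bands = [
        SpectralBand("bleach", bleach_center, fwhm, a0 * phi, compartment=BLEACH),
        SpectralBand("product", product_center, fwhm, -0.85 * a0 * phi, compartment="ELF"),
    ]
    early = band_matrix(early_bands, wn).sum(axis=0)
    late = band_matrix(late_bands, wn).sum(axis=0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        early = early + rng.normal(0.0, noise_sigma, size=wn.shape)
        late = late + rng.normal(0.0, noise_sigma, size=wn.shape)
    return wn, early, late


# ---------------------------------------------------------------------------
# Toy dipole trajectories (oracle source for the spectral-density module)
# ---------------------------------------------------------------------------


def langevin_dipole_trajectory(
    omega0: float,
    friction: float,
    coupling: float,
    dt: float,
    n_steps: int,
    temperature: float = 300.0,
    seed: int = 0,
    mass: float = 1.0,
):
    """Thermalized damped-harmonic dipole trajectory (3 independent components).

    Parameters
    ----------
    omega0, friction:
        Harmonic frequency and friction, both in cm^-1 (angular quantities
        divided by 2 pi c). ``omega0 = 0`` gives an overdamped
        Ornstein-Uhlenbeck dipole.
    coupling:
        Dipole amplitude scale (e A). Reduced units are used such that the
        stationary per-component dipole standard deviation is
        ``coupling * sqrt(T / 300 K)`` (equipartition in reduced units).
    dt, n_steps:
        Time step (fs) and length.
    mass:
        Effective oscillator mass relative to the default; the spectral peak
        scales as 1/sqrt(mass).

    Returns a :class:`~photokin.specdens.DipoleTrajectory`.
    """
    from .specdens import DipoleTrajectory  # local import: avoid cycle

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_steps <= 2:
        raise ValueError("n_steps must be > 2")
    rng = np.random.default_rng(seed)
    two_pi_c = 2.0 * np.pi * C_CM_PER_FS
    w0 = omega0 * two_pi_c          # rad/fs
    gam = friction * two_pi_c       # 1/fs
    sig_p = coupling * np.sqrt(temperature / 300.0)
    p = np.zeros((n_steps, 3))
    if coupling == 0.0:
        traj = p
    elif w0 == 0.0:
        # exact OU update
        a = np.exp(-gam * dt / max(mass, 1e-300))
        b = sig_p * np.sqrt(1.0 - a * a)
        x = rng.normal(0.0, sig_p, size=3)
        for i in range(n_steps):
            p[i] = x
            x = a * x + b * rng.normal(size=3)
        traj = p
    else:
        # BAOAB splitting for m xdd = -k x - gamma xd + noise, k = m (w0/sqrt(m))^2
        m = mass
        k_spring = w0 * w0          # with m=1 the peak sits at omega0
        kT = sig_p * sig_p * k_spring   # <x^2> = kT/k_spring = sig_p^2
        c1 = np.exp(-(gam / m) * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT / m)
        x = rng.normal(0.0, sig_p, size=3)
        v = rng.normal(0.0, np.sqrt(kT / m), size=3)
        half = 0.5 * dt
        for i in range(n_steps):
            p[i] = x
            v = v - half * (k_spring / m) * x
            x = x + half * v
            v = c1 * v + c2 * rng.normal(size=3)
            x = x + half * v
            v = v - half * (k_spring / m) * x
        traj = p
    return DipoleTrajectory(
        dt=dt, dipole=traj, temperature=temperature, volume=0.3,
        isotope_label="H2O",
        meta={"omega0_cm": omega0, "friction_cm": friction, "coupling": coupling,
              "seed": seed, "mass": mass},
    )
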