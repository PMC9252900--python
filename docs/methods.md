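# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `photokin`, and what the synthetic-data tests do and do not
demonstrate about measured data.

## Compartment kinetics

The photocycle is a directed acyclic graph of compartments with first-order
decay: `dc/dt = K c`, where `K` has `-1/τ_i` on the diagonal and
`b_{i→j}/τ_i` on feeding edges. Branching fractions out of every
non-terminal state sum to one; the initial populations sum to one. The
solution is a sum of pure exponentials obtained by eigendecomposition.

- **Degenerate rates.** If two decay rates coincide within 1e-9 relative,
  one is perturbed by 1e-6 relative rather than switching to a `t·e^{−kt}`
  basis. The induced error (checked against adaptive ODE integration) is
  below 1e-4 in population, far inside experimental resolution.
- **IRF convolution.** Each exponential is convolved analytically with the
  Gaussian instrument response. Numerically the kernel is evaluated as
  `½ e^{−Δ²/2σ²} erfcx(z)` with `z = (kσ² − Δ)/(σ√2)`, switching to the
  direct product for `z < −6` to avoid `erfcx` overflow at late times. The
  `k = 0` case gives the IRF-broadened step used for terminal sinks.
- **Default scheme.** S₁ →(50 fs, 0.5/0.5)→ {ES_prot, ES_deprot};
  ES_prot →(150 fs)→ GS\*; ES_deprot →(1.5 ps)→ {ELF 0.7, GS\* 0.3};
  GS\* →(4 ps)→ S₀. ELF and S₀ are terminal in the ≤15 ps window; S₀ is the
  recovered ground state. GS\* is fed by both branches; this is
  configurable by editing the scheme.
- **Quantum yields** are path-sums of branching products, memoized over the
  DAG; terminal-state yields sum to one by construction.

## Global lifetime analysis (variable projection)

For trial time constants the design matrix `X` holds the IRF-convolved
exponentials (plus, by default, a non-decaying column that absorbs
long-lived photoproduct signal). The per-wavenumber amplitudes solve
`min‖D − XC‖` exactly (one `lstsq` for all pixels); only the time constants
— and with `fit_irf`, t₀ and the IRF width — are iterated
(`scipy.optimize.least_squares`, TRF). Consequences:

- DAS equal the per-pixel ordinary least-squares solution at fixed rates
  (tested as an invariant).
- The fit is idempotent on its own reconstruction to <1e-8 relative.
- Uncertainties come from the local quadratic approximation
  (`s² (JᵀJ)⁻¹` on the varpro cost). Components faster than the IRF FWHM
  are flagged **IRF-limited** and their uncertainty is floored at ±τ: a
  50 fs step under a 60 fs response is bounded, not resolved. (The FWHM —
  not σ — threshold is deliberate; a component slower than σ but faster
  than the response width is still not resolvable in practice.)
- Significance: the largest per-pixel amplitude/uncertainty ratio of each
  component must exceed 5; pure-noise inputs are flagged, not silently fit.
- When no initial guesses are given, 8 deterministic log-spaced guess
  ladders spanning the delay range are tried and the best cost kept.
- Delays earlier than `t₀ − 5σ` are excluded from the cost by default
  (perturbed free-induction-decay signals are outside the model); the
  returned residual matrix still covers the full grid so that
  `model + residuals == data` exactly.

## Target analysis

Writing the scheme solution as `P = A E` (states × modes amplitude matrix
times exponential basis) and the fitted model as `X C`, matching components
to eigenrates gives `C = Aᵀ S`, solved for the species-associated spectra
`S`. Two structural points:

- The recovered electronic ground state carries zero difference signal by
  definition of a difference spectrum; its row is removed before inversion.
  This also removes the sink degeneracy of schemes with two terminal states
  (ELF and S₀ share eigenvalue zero but remain distinguishable because S₀
  is constrained).
- Modes with no amplitude in any observed state (e.g. the zero-rate mode of
  a scheme whose only sink is the ground state) are dropped together with
  the matching fitted component. A residual non-square or ill-conditioned
  amplitude matrix is reported as an unobservable-state error, never
  silently pseudo-inverted.

## Synthetic data

The simulator emulates: multiexponential compartment kinetics under a
Gaussian IRF (40–300 fs FWHM across VIS/IR configurations), Gaussian /
Lorentzian bands and an error-function-edged flat plateau for the broad
continuum band (1,750–1,900 cm⁻¹, attached to the deprotonated
excited-state branch so it rises within ~300 fs under the 250 fs IR
response without an extra rate constant), ground-state bleach attached to
the summed transient population, band-specific dichroism
(`par = iso(1+2r)`, `per = iso(1−r)`, `r = 0.2(3cos²θ−1)`), damped coherent
oscillations, additive white Gaussian noise, and Henderson–Hasselbalch
amplitude titration (Hill coefficient fixed at 1, one protonatable group).

- **Oscillations** are injected as the *exact* Gaussian-IRF convolution of
  each damped cosine, computed with the complex-rate kernel
  (`erfcx(z) = wofz(iz)`). An earlier design multiplied the cosine by the
  ES_prot population envelope; that conflates the 150 fs population decay
  with the oscillation's own damping (effective ~77 fs instead of the
  nominal 160 fs) and was dropped. The ES_prot assignment survives as the
  spectral profile of the oscillatory residual; oscillations are only added
  to the VIS configuration in practice since the ~250 fs IR response cannot
  resolve them.
- **Band tables.** VIS defaults place bleach/SE1/SE2/ESA/GS\*/ELF bands at
  the reported positions (SE1 ~12,900, SE2 ~11,000, GS\* 12,435 cm⁻¹ ...);
  widths and amplitudes are free generator parameters chosen to resemble
  the measured spectra — they are *not* fitted quantities. The IR table
  holds the ring-D carbonyl triplet (bleach 1,684 / excited state 1,666 /
  product 1,692 cm⁻¹), the propionic-side-chain-C triplet (1,743 / 1,727 /
  1,735 cm⁻¹) and the CB plateau with a 34° TDM angle.
- **Noise** is white and per-point; correlated baseline noise is out of
  scope. Identical seeds give bit-identical datasets; the `both` channel
  draws par then per and builds iso = (par+2per)/3 from the noisy channels.
- **What passing tests do not show:** real data add chirp/dispersion of the
  broadband probe (uncorrected here), correlated baseline drifts,
  pixel-dependent noise, depolarization by overlapping bands and
  perturbed-free-induction-decay signatures before t₀. Recovery results on
  this generator are necessary, not sufficient, evidence for performance on
  measured spectra.

## Anisotropy and TDM angles

`r(t)` is computed per point, masked where `|par + 2·per|` is below 3× the
per-point noise (estimated robustly from second differences along delay if
not given; the masked fraction is reported), band-averaged, then averaged
over a stated delay window — default 0.4–0.6 ps, matching the window used
for continuum-band snapshots — before inversion
`θ = arccos √((5r+1)/3)` with first-order error propagation. Values outside
[−0.2, 0.4] are flagged, never clamped. Depolarization by overlapping bands
is not corrected; the reported ±10° class of uncertainty on measured CB
angles subsumes it.

## Coherent oscillations

The primary estimator is the time-domain fit
`Σ Aᵢ e^{−t/τᵢ} cos(2πc ν̃ᵢ t + φᵢ)` (c = 2.99792×10⁻⁵ cm/fs): a 300/340
cm⁻¹ doublet damped with 160 fs beats at ~0.8 ps and is poorly separated by
an FFT over a ~2 ps window, so the Hann-windowed, 4×-zero-padded FFT map is
diagnostic only. Amplitude and phase are linear (varpro again); frequency
and damping are bounded (ν̃ ≥ 1 cm⁻¹, Nyquist above; 2 fs ≤ τ ≤ 50× span)
and multi-started deterministically: every n-subset of 12 log-spaced
frequency seeds over 100–700 cm⁻¹ plus an FFT-peak-based start.

Two optional refinements handle full simulations: an IRF-convolved basis
(same complex kernel as the generator) for traces that include the onset,
and nuisance background columns — the global fit's own exponential basis —
co-fitted linearly. The latter is exact in the noiseless limit: the
residual equals the injected oscillation plus a term in the span of the
kinetic design matrix, so projecting that span out deconfounds the
oscillation parameters. Slow (≳1 ps) damping components can still alias
with kinetic misfit; this is flagged as a known limitation rather than
resolved.

## Bands, quantum yield, titration

Band fits refine amplitude/center/width subsets per band (lmfit
Levenberg–Marquardt) with a free constant baseline (IR baselines drift);
template bands whose center lies more than 2 FWHM outside the data are
rejected. The bleach-ratio quantum yield fits the early spectrum (bleach +
excited-state companion) and the late spectrum (bleach + product companion,
widths fixed to the early fit — same-mode bands share widths), and ratios
the bleach amplitudes; amplitude mode is the default, area mode
(amplitude × FWHM) is available. The estimate is invariant under common
rescaling of both spectra. Late means 10–15 ps (the ultrafast reaction is
complete), early 0.1–0.2 ps.

The continuum-band transient is the per-delay mean over 1,772–1,832 cm⁻¹
with optional width-5 moving-median smoothing (raw trace always kept). The
pKa fit is a weighted least-squares Henderson–Hasselbalch sigmoid with
Hill = 1; a fitted pKa more than 1 unit outside the sampled range is
flagged extrapolated, and a plateau separation below 3× the residual noise
is flagged ill-conditioned.

## Spectral power density

`C(t)` is the unbiased FFT-based vector autocorrelation of the dipole
(e·Å); `C(ω)` is estimated per component by Welch's method (default 4
half-overlapping Hann segments; `n_segments=1, window="boxcar"` recovers
the Parseval-consistent periodogram) and summed. The susceptibility
prefactor `ω/(2 k_B T V ε₀)` is applied in SI units (e·Å = 1.60218e-29 C·m,
k_B = 1.38065e-23 J/K, ε₀ = 8.85419e-12 F/m, c = 2.99792e-5 cm/fs) and the
axis converted to cm⁻¹; the reported quantity is ω·χ″(ω). Spectra scale
exactly as 1/V and 1/T, and linearly in dipole-squared amplitude.
Optionally the first 0.1 ps of a trajectory can be truncated (fast initial
equilibration). Isotopologue comparison reports only
normalization-invariant metrics (normalized L2 distance, integrated-power
ratio, centroid shift) over a window defaulting to the continuum-band
region, because absolute scales of computed spectra are arbitrary.

The Langevin generator is the oracle: a thermalized damped-harmonic dipole
(BAOAB integration; exact Ornstein–Uhlenbeck updates when ω₀ = 0),
initialized from the stationary distribution. Reduced units fix the
stationary per-component dipole standard deviation at
`coupling · √(T/300 K)`, making equipartition directly checkable; ω₀ and γ
are given in cm⁻¹ so that ω·χ″ peaks exactly at ω₀ with FWHM γ. Line
parameters are extracted by fitting the analytic shape with uniform
*relative* weights (PSD estimates have constant relative error), averaging
several independent trajectories — mirroring the practice of averaging
independent short runs.

## Scan handling and I/O

Repeated scans are combined by a per-point symmetric trimmed mean (default
10% total, 5% per tail), which is permutation-invariant and reports
rejected counts; backgrounds measured far before time zero (~−60 ps) are
subtracted per wavenumber. Dataset files are plain text (wavenumber header
row, delay first column, sniffed comma/tab dialect, 17-significant-digit
values so round trips are bit-identical); delays are stored in ps,
wavenumbers in cm⁻¹, ΔA in mOD. Mixed-polarization composites are declared
via a `channel_map` header entry, never guessed. Every CLI report starts
with a reproducibility block (version, config hash, seed).

## Acceptance experiments and problem sizes

`photokin.experiments` fixes the canonical conditions: VIS recovery uses 80
probe pixels × 120 delays, 60 fs IRF, noise at 1% of peak, 10 seeds, fit
initialized at twice the truth; the bleach-ratio study uses 20 seeds at 2%
peak noise and isomerization fraction 0.33; the titration study 8 pH points
over 6.6–8.4 with 5%-of-span noise, 10 seeds; oscillation recovery 20
seeds of 10 fs-sampled 2 ps traces at 1% peak noise; the spectral-density
oracle averages five 40 ps trajectories (dt = 0.25 fs). These sizes keep
the full acceptance run below a minute on one CPU while leaving every
recovered quantity's Monte-Carlo error well inside its assertion band.

## Known limitations

- No chirp correction, no lifetime-distribution analysis, no
  linear-prediction/wavelet oscillation methods, no Voigt profiles, no
  rotational-diffusion modelling of r(t) (protein tumbling is far slower
  than the 15 ps window).
- The ε-perturbation for degenerate rates limits population accuracy to
  ~1e-4 in exactly-degenerate schemes.
- The Langevin reduced-unit convention makes absolute spectral amplitudes
  arbitrary; only shapes, positions and scaling laws are meaningful.
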