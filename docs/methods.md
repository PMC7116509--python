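# Methods

## Exchange model

A binding scheme is a small continuous-time Markov chain over protein
states (free, bound, open, closed, monomer, dimer subunits, ...). At each
titration point the equilibrium is solved analytically per free-ligand
concentration [L]: every scheme in the library gives closed-form *relative*
state populations at fixed [L], and [L] itself is found by a bracketed
Brent root search of the ligand mass balance on [0, L_tot] (a guaranteed
bracket; two-state and monomer–dimer use their closed forms directly, and
the two-state closed form is written in the cancellation-free form of the
quadratic root so it stays accurate when protein is in large excess).
Populations always sum to one by construction.

The exchange rate matrix **K** has element (i, j) equal to the first-order
rate from state j into i; association steps use pseudo-first-order rates
k_on·[L] with k_on = k_off/K_d always derived, never fitted independently.
Because every scheme is parameterized through equilibrium constants, each
transition pair satisfies detailed balance and **K**·p_eq = 0 holds to
rounding error — this is verified per model over random parameter draws.

Model conventions where the scheme leaves freedom:

- *Induced fit / conformational selection*: `k_close` is the closing rate
  (PL_open → PL_closed, or P_open → P_closed) and `k_open` the opening
  rate, so closed:open population ratios are k_close/k_open (bound) and
  k_open/k_close (free), respectively.
- *Four-state exchange*: ligand affinity is specified as the apparent
  K_d,app of (A+B) + L ⇌ (AL+BL); the site constants follow from detailed
  balance, K_d,A = K_d,app(1+K_AB′)/(1+K_AB) and
  K_d,B = K_d,A·K_AB/K_AB′. The A↔B splits are
  k_AB = k_ex·K_AB/(1+K_AB), k_BA = k_ex/(1+K_AB), likewise primed.
- *Dimerization*: 2M ⇌ D is represented with two dimer spin states
  (M, D1, D2) so asymmetric dimers can carry distinct shifts; a tagged
  monomer enters either subunit at k_on[M] and leaves at k_off, with
  K_d = [M]²/[D]. For a symmetric dimer, link the D1/D2 resonance
  parameters through shared variables — the three-state simulation then
  reduces exactly to the lumped two-state one (verified to 1e-9).
- *Two binding sites*: K_d1 (P⇌B1), K_d2 (P⇌B2), K_d3 (B1⇌B12) are free;
  cycle closure fixes K_d4 = K_d1·K_d3/K_d2 (B2⇌B12). The association
  rate constant of the P⇌B2 step is k_off2/K_d2 by default
  (`kd2_pairing="kon2"`); the alternative `"kon3"` pairing shares the
  B1→B12 association constant and derives that step's dissociation rate
  from K_d2, preserving the equilibrium. Both pairings give identical
  equilibria and stationary rate matrices; only the kinetics of that one
  step differ.
- *Flexible stoichiometry*: P + nL ⇌ PL treats n as a continuous
  parameter: the ligand mass balance consumes n·[PL] and association is
  Hill-type, k_on[L]^n with k_on = k_off/K_d^n. It is meant to absorb
  ligand-stock concentration errors, not to model true multi-site binding.

Concentrations are molar internally; `uM`/`mM` constants and the YAML/CLI
layer (which speaks µM) cover the interfaces.

## Virtual spectrometer

Magnetization lives on the composite (spin × state) basis of a spin group;
exchange acts as I ⊗ **K** and never mixes different spins. Pulses are
ideal and instantaneous; relaxation and exchange act during delays and
acquisition only. Evolution generators:

- acquisition (t2): i·diag(Ω_H ± π·J_HNHA) − diag(R2I) + K, the two
  J-doublet components detected with weight ½ each (J_HNHA defaults to
  6.5 Hz, set 0 for perdeuterated samples);
- HSQC t1: single-quantum ^15N, i·diag(Ω_N) − diag(R2S) + K;
- HMQC/SOFAST-HMQC t1: zero- and double-quantum generators
  i·diag(Ω_N ∓ Ω_H) − diag(R2S) + K with the mid-t1 ^1H 180° implemented
  as a ZQ↔DQ swap (both orders averaged), so the net t1 frequency is Ω_N
  while exchange broadening acts on both coherences — this is what makes
  HMQC indirect lineshapes broader than HSQC ones whenever the ^1H shift
  difference is nonzero, and exactly equal when it vanishes.

Transfers: INEPT periods of duration 2δ (δ = 1/(4·J_IS), J_IS default
92 Hz) propagate exchange on the transverse-^1H generator and scale by the
J-transfer amplitude sin(π·J_IS·2δ); optional zz-filter delays use the
longitudinal generator (exchange only); optional gradient-selection delays
use the transverse-^15N generator. Both default to zero, to be set from
the pulse program actually used. The SOFAST-HMQC selective refocusing is
modelled as ideal (J_HNHA inactive in t1); longitudinal-relaxation
enhancement is not modelled — full recovery between scans is assumed.

Initial amplitudes are equilibrium fractions × P_tot × ns × rg, which fixes
the absolute scale of every spectrum in a titration and removes any need
for per-peak or per-spectrum normalization.

t1 uses States quadrature with a half-dwell initial delay: the cos/sin
components are the real/imaginary parts of the propagated coherence, and
processing applies the matching −90°/180° first-order phase pair. With
this convention an exchange-free resonance processes to an *exactly*
symmetric absorptive discrete Lorentzian (the TPPI sign alternation of
States-TPPI cancels between simulation and processing and is therefore
omitted). Indirect-dimension shifts outside the sweep width are wrapped
modulo SW (folded peaks are fitted at their aliased positions); the direct
dimension is not folded.

Matrix exponentials on time grids use eigendecomposition, falling back to
scipy's scaling-and-squaring stepwise propagation when the eigenvector
matrix is ill-conditioned (condition number > 1e12).

## Processing

Per dimension: multiply by exp(−π·lb·t), scale the first point (0.5 for
t=0-sampled dimensions, 1.0 for the half-dwell t1), zero-fill (default
twice the acquired size), complex FT (no forward normalization; point i of
an N-point axis sits at (N/2 − i)·SW/N relative to the carrier, matching
the NMRPipe axis convention ORIG = OBS·CAR − SW/2 + SW/N), phase, discard
imaginaries. Direct-dimension extraction slices a ppm window and updates
the axis metadata consistently. Linear prediction is deliberately not
implemented: simulations are synthesized directly out to the post-LP grid
declared in the configuration, which is all the comparison requires.
Solvent filtering and baseline correction belong to the upstream
processing of experimental data; simulations contain neither solvent
signal nor baseline.

Noise is estimated per spectrum by maximum likelihood on a truncated
zero-mean Gaussian: starting from 1.4826 × MAD, points with |I| below
3 × the current σ are retained and σ re-estimated by maximizing the
truncated likelihood, iterating to a relative change < 1e-6. The 3σ
truncation factor is a convention (the exclusion of "intense regions" has
no canonical threshold) and can be overridden, as can σ itself.

## Fitting

χ² = Σ_s Σ_{p∈ROI(s)} (I_obs − I_sim)²/σ_s². ROIs are ppm polygons
rasterized with an even-odd, boundary-inclusive rule (deterministic under
vertex reordering); spins sharing a group label are simulated jointly over
the union of their ROIs. Parameters pack into a flat vector labelled
`ASSIGNMENT_QUANTITY_STATE`; shared variables appear once and fan out to
all linked targets on unpacking. New spins start at R2 = 20 s⁻¹.

Optimization is scipy's trust-region-reflective least squares with box
bounds, finite-difference Jacobian, ftol 1e-8 / xtol 1e-10 and at most 300
iterations; with a numerically differentiated residual, tighter tolerances
only buy noise-floor crawling. Trust-region scales are physical (≈0.03 ppm
for ^1H shifts, 0.2 ppm for ^15N, 10 s⁻¹ for linewidths, the parameter
magnitude for model constants) — scaling by raw parameter values lets the
optimizer throw peaks out of their ROIs onto flat plateaus. The covariance
is (JᵀJ)⁻¹ at the optimum, computed via diagonally preconditioned
pseudo-inverse; parameters within 1e-8 of a bound are flagged as
unconstrained. Fitting is deterministic given data and starting values.

The two-stage protocol fits the free-state resonance parameters against
the first (ligand-free) spectrum, then pins the free-state chemical shifts
(linewidths may still refine) and fits bound-state resonances plus the
binding constants globally.

Bootstrap: residuals over each spectrum's pooled ROI points are resampled
with replacement, added to the best-fit surface, and the fit repeated from
the *original* starting vector; means, standard errors and the parameter
covariance/correlation matrix are reported, and the model is restored to
the best fit afterwards. Pooling per spectrum (rather than per ROI) is a
convention; with ≥50 replicas the two differ little.

## Synthetic data

The generator emulates a real titration: a ligand-equivalents schedule is
converted to aliquot volumes from a concentrated stock with full dilution
bookkeeping (or constant protein if the stock contains protein), each
point is simulated from ground-truth parameters, complex Gaussian noise is
added in the **time domain** (so processing shapes the noise exactly as it
does for real data; the amplitude is calibrated through a noise-only
processing pass so σ is specified in final-spectrum units, or via a target
SNR), and the spectra are processed and optionally written as .ft2 files
with a manifest the CLI can fit directly. A fixed seed reproduces the
series byte for byte.

Default study conditions: 100 µM protein, 550 µL, 10 mM ligand stock,
equivalents (0, 0.1, 0.25, 0.4, 0.6, 0.85, 1.15, 1.5, 1.9) — stored as a
literal list — K_d = 20 µM, k_off = 100 s⁻¹, two amide spins sampling
slow-intermediate and fast exchange, 64 (t1) × 128 (t2) complex points at
700 MHz. These grids are far below experimental sizes; they keep a full
generate → fit → bootstrap cycle in minutes while exercising every code
path. What passing tests on such data shows is internal consistency of
the whole pipeline (simulation, processing, optimization, error analysis)
— not robustness to baseline distortions, solvent artifacts, temperature
drift, assignment errors or model misspecification, none of which the
generator emulates.

The Monte-Carlo/bootstrap calibration study is smaller still (one spin,
five points, 32 × 64 points, no zero-fill, no apodization). Two numerical
facts motivate the last two choices. First, zero-filling and apodization
*correlate* frequency-domain noise, while residual resampling treats
residuals as exchangeable; at the acquired grid with lb = 0 the noise is
white and the bootstrap SE matches the scatter over independent noise
realizations (verified within a factor 1.5). With experimental-style
processing the pooled bootstrap understates errors by roughly the noise
oversampling factor — a known limitation of residual resampling, worth
remembering when interpreting bootstrap errors on heavily zero-filled
data. Second, without apodization a strongly truncated line has sinc
sidelobes, which can create shallow local minima in peak-position
parameters; fits on such grids should start within about one point
spacing of the truth (the apodized default study does not have this
problem).

## Limitations

- TROSY, sensitivity-enhanced and in-phase HSQC, and ^13C-detected
  experiments are excluded by design (transfer dynamics outside the
  model); requesting them raises an explicit error.
- Pulses are ideal; exchange during pulses, off-resonance effects, water
  suppression artifacts and solvent-exchange broadening are not modelled.
- R2I/R2S are effective decay rates absorbing in-phase/anti-phase mixing
  and J-mismatch; they should not be over-interpreted as true relaxation
  rates, and initializing them from relaxation experiments buys little.
- Direct-dimension folding is unsupported (indirect folding is).
- Exact FHSQC zz-filter/gradient durations depend on the pulse program
  used; the defaults (zero) must be overridden to match it.
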