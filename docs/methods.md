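# Methods

## The problem

Channelrhodopsins are light-gated cation channels; several widely used
variants (e.g. CheRiff) conduct protons as well as Na⁺/K⁺. In a polarized
cell the inward proton-motive force is large, so sustained optogenetic
stimulation can acidify the cytosol — from a resting pH of ~7.3 down by
several tenths of a pH unit within minutes — while engineered low-proton
variants (ChR2-3M-like, PsCatCh2.0-like) depolarize without acidifying.
`optoacid` models this process mechanistically, simulates the imaging
experiments that measure it, and implements the analysis chain that turns
interleaved stimulation/imaging movies into calibrated pH kinetics.

## Single-compartment forward model (`core_model`)

A compartment (sphere of radius r, surface-to-volume 3/r, or cylinder,
2/r) is well mixed; there is no intracellular diffusion PDE, no GHK flux
equation, and no multi-state photocycle. The chain is four linear ODEs
driven by the light schedule:

1. **Gating.** Open fraction h relaxes toward
   a∞ = s(λ)·P/(P + EPD50) with time constant
   τ_on(P) = τ_on,sat·(1 + EPD50/P) while the stimulation light (power
   density P, wavelength λ with relative sensitivity s(λ), s(488 nm) = 1)
   is on, and decays with τ_off after light-off. A multiplicative
   desensitization factor d relaxes from 1 toward the steady/peak current
   ratio (τ_desens, default 1 s) under light and back in the dark; the
   activation is a = h·d. This reproduces the peak-then-sag step response
   with a single multiplicative step rather than an extra photocycle
   state. The τ_on(P) form is a modelling choice that makes opening
   kinetics intensity-dependent with τ_on → τ_on,sat at saturation, as
   observed; no functional form is established experimentally.
2. **Voltage.** C_m dV/dt = −g_leak(V − E_K) − g_max·a·(V − E_ops). The
   leak is Kir2.1-dominated (E_K = −70 mV), so the resting potential is
   ≈ −70 mV and stimulation pulls V toward the conductance-weighted mean.
3. **pH.** A fraction f_H of the opsin current is carried by protons
   (a lumped phenomenological parameter, not a permeability ratio;
   defaults: 0.5 for the proton-conducting opsin, 0 for the proton-tight
   ones). dpH/dt = I_H/(F·Vol·β) + k_rec(pH_rest − pH), with I_H in the
   inward-negative convention, β the buffering capacity and k_rec a
   first-order stand-in for Na⁺/H⁺ exchange. At fixed membrane current
   density the initial acidification rate is proportional to the
   surface-to-volume ratio — the reason thin dendrites acidify faster
   than somata.
4. **Fluorescence.** The reporter follows a Hill protonation curve
   F = F_max/(1 + 10^(n(pKa − pH))) with pKa 7.5 and n = 1 (only the pKa
   is constrained experimentally), plus a blue-light photoartifact that
   accumulates linearly with cumulative blue dose, plus Gaussian noise
   (seeded; noise_sd is expressed in ΔF/F units of the first clean
   sample). Whether the artifact saturates or accumulates linearly is not
   known; linear accumulation is assumed and isolated in one parameter.

### Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| β (buffering) | 20 | mmol L⁻¹ pH⁻¹ | typical cytosolic range; no measured value exists for these cells |
| k_rec | 0.003 | s⁻¹ | makes half-recovery ≈ 230 s, slower than the 150-s observation window, matching the slow incomplete recovery seen experimentally |
| C_m, g_leak | 20 pF, 2 nS | — | generic polarized cell |
| g_max (conducting opsin) | 3 | nS | with f_H = 0.5 yields a 150-s pH drop of ≈ 0.48, inside the measured 0.3–0.8 envelope |
| stim intensity | 500 | mW cm⁻² | middle of the 400–800 range used experimentally |
| artifact_rate | 1.70×10⁻³ | ΔF/F per J cm⁻² | calibrated once so an opsin-negative control under the canonical protocol (25 J cm⁻² total blue dose) shows +0.11 ΔF/F — a stated design decision, not a prediction |
| sensor pKa, n | 7.5, 1 | — | pKa measured; Hill slope not reported, 1 is the standard single-site default |

The compartment is treated as non-spiking: membrane parameters of neurons
during stimulation (spiking vs clamped) are not characterized, so the
simulator deliberately does not guess at spike-driven conductances.

### Integration

`step_voltage`/`step_pH` expose fixed-step explicit Euler with a checked
stability bound (dt ≤ C_m/(g_leak + g_max·a); violations raise an error
naming the bound). `simulate_cell` instead advances each linear stage with
its per-step exponential update (exact for coefficients frozen over the
step, unconditionally stable), evaluated as a chunked linear recurrence so
a 300-s protocol at dt = 1 ms runs in well under a second; coefficient
freezing makes the composite scheme first-order accurate. Both paths are
tested against the closed-form single-exponential voltage solution and an
analytic proton-bookkeeping integral.

## Gap-junction monolayer (`monolayer`)

Cells are lumped nodes on a square lattice (pitch 20 µm) with 4-neighbor
ohmic coupling and no-flux boundaries, matching electrotonic-continuum
behaviour when the length constant λ = pitch·√(g_gap/g_leak) far exceeds
the pitch. λ ≈ 300 µm (a literature value for these monolayers) is
reproduced with g_gap/g_leak = 225 — that pair is the implementer's
choice, documented here, since only λ itself is constrained. Gap-junction
proton exchange is orders of magnitude slower than voltage spread and
defaults to zero (config knob `k_gapH` for sensitivity analysis).

`step_field` is explicit Euler on the coupled system with a stability
bound C_m/(g_leak + g_max·a + 4g_gap). At the 100×100/λ = 300 µm scale
that bound is ~10 µs, so `simulate_monolayer` instead exploits the
timescale separation (voltage settles in milliseconds, pH evolves over
seconds): the steady-state voltage field is obtained by a sparse linear
solve per illumination phase and the slow pH balance is integrated on
top with the protocol's stimulation duty cycle (default 1/3, the
0.5-s-on/1-s-off cadence). The two paths agree on small grids.

The **counterfactual mode** (`VoltageGatedProtonParams`) reroutes the
proton path through a Boltzmann-gated conductance present in *every*
cell. Under 95-µm stripes, voltage spreads almost uniformly
(off-stripe depolarization ≈ 95% of on-stripe), so opsin-bound proton
flux confines acidification to the illuminated stripes (on/off ratio
≳ 300 with k_gapH = 0) while the voltage-gated counterfactual produces a
ratio of ≈ 1. This is the discriminating logic of the striped-
illumination experiment; the mode exists only to demonstrate it.

## Analysis pipeline (`pipeline`)

Conventions follow the interleaved-protocol analysis: frames during
stimulation are discarded and frames within each imaging epoch averaged
(timestamp at the epoch midpoint); F₀ is the first collapsed frame; ΔF/F
is computed over pixels whose F₀ exceeds a threshold (default: median of
nonzero pixels; absolute and Otsu rules available); the population-mean
control ΔF/F (opsin-negative cells) is subtracted in ΔF/F space *before*
pH conversion; a strictly monotone piecewise-linear calibration anchored
at (pH 7.3, ΔF/F 0) is inverted to convert ΔF/F to pH, assuming an
initial pH of 7.3 per cell (overridable); out-of-range values are clamped
to the end knots and flagged rather than extrapolated, because linear
extrapolation of a saturating sensor is unbounded.

Kinetics: the acidification half-time is the first, linearly
interpolated, crossing of half the maximum ΔF/F decrease within the
stimulation window; recovery is a least-squares single exponential
y∞ + (y₀ − y∞)e^(−(t−t₀)/τ) initialized with y∞ from the last 10% of the
window and τ from log-linear regression, fit on the *calibrated pH*
course so the sensor nonlinearity does not bias τ; half-recovery time is
τ·ln 2. Group comparisons are two-sided Wilcoxon tests (rank-sum
unpaired, signed-rank paired; sidedness is a package convention), exact
for small tie-free samples (n ≤ 10 unpaired, n ≤ 15 paired) and
normal-approximation with tie correction otherwise, via `scipy.stats`;
the exact path is verified against full enumeration of rank assignments.

### Numerical caveats quantified by the tests

- **Calibration interpolation error.** With knots at the measured buffer
  steps {6.4, 6.7, 7.0, 7.3}, the piecewise-linear inverse of the Hill
  sensor incurs a maximum round-trip error of 0.0205 pH (at pH ≈ 6.55,
  the most curved segment). Denser knots reduce this quadratically
  (≈ 0.002 at 0.1-pH steps); the knot set is configuration-driven.
- **Recovery-fit identifiability.** With k_rec = 0.003 s⁻¹ (τ ≈ 333 s), a
  150-s recovery window observes only a third of the recovery and leaves
  τ/y∞ nearly degenerate: systematic distortions of a few 10⁻⁴ pH (e.g.
  coarse-calibration kinks) shift the fitted τ by ~20%. Parameter-recovery
  validation therefore uses a 400-s recovery observation and the 0.1-pH
  calibration; with those, the pipeline recovers τ to 0.6% and the pH
  minimum to 0.004 (medians over 30 cells). Fits on short windows should
  be read as half-recovery-time summaries, not τ estimates — which is how
  the experimental analysis uses them.

## Photocurrent characterization (`ephys`)

Voltage-clamp traces (t in ms, I in pA) are smoothed with a centred
moving average (default 5 samples; edges shrink symmetrically). I_peak is
the extremal current in the light window, I_ss the mean of its last 20%
(the averaging window is a package convention), and the ratio is computed
and labelled I_SS/I_peak — 1.00 for a sag-free step; published gating
tables sometimes print the same numbers under the inverted heading.
Opening/closing time constants are single-exponential least squares, with
a relative-RMSE flag (> 5% of amplitude) marking misspecification such as
two-exponential decays. Light sensitivity is fit as
I_ss(P) = I_max·P/(P + EPD50) with a seeded bootstrap CI. The reversal
potential interpolates the zero crossing of the I–V series and refuses to
extrapolate. Action spectra normalize steady currents to the 488-nm
reference, reporting values under 0.3% of it as below the detection
floor. Ion-substitution selectivity uses the ideal Nernst shift
(RT/zF)·ln(c_after/c_before); the selectivity index is measured/ideal,
and no absolute GHK permeability ratios are computed. No liquid-junction,
series-resistance, or capacitance-transient corrections are modelled.

## What the synthetic data does and does not emulate

The generators reproduce: interleaved 488-nm stimulation / 561-nm imaging
epochs; compartment-size-dependent acidification; sensor protonation with
pKa 7.5; the positive blue-light photoartifact in opsin-negative controls;
shot-like Gaussian noise at trace and pixel level; and gap-junction-
coupled monolayers under striped illumination. They do not emulate:
motion, bleaching beyond the linear artifact, spiking, intracellular
proton diffusion, heterogeneous gap junctions, cell-shape irregularity,
or voltage-dye photophysics (monolayer voltage maps are reported in mV).
Passing tests therefore validate the analysis chain and the model's
internal consistency, not the biological parameter values themselves:
the headline experimental numbers (final pH per opsin, gating constants)
are measurements, and the package treats them as calibration envelopes
or constructed inputs, never as predictions.

## Problem sizes

Default validation sizes: 300-s single-cell protocols at dt = 1–2 ms,
cohorts of 25–30 cells, 100×100 monolayers, 50-replicate fit ensembles —
sizes at which every stage is exercised end to end while the full suite
runs in well under a minute.
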