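# Methods

This note records the models implemented in `itdispersion`, their
assumptions, the default parameter values and why they were chosen, the
numerical choices, and the known limitations — in particular what the
synthetic tracer generator does and does not emulate about real bench
recordings.

## Physical picture and coordinate conventions

An intrathecal bolus injected at the lumbar level spreads along the
spinal subarachnoid space. Oscillatory CSF motion plus mixing around
nerve roots make the axial spreading behave like an effective diffusion
process with coefficient D of order cm²/min — far above the molecular
diffusivity D0 of the tracer. The analysis domain is one-dimensional and
injection-centric: x = 0 at the injection site, the closed sacral end of
the dural sac at x = −6 cm, and the canal extending to x = +59 cm
cranially (65 cm total, the cisterna magna–S3 distance of the packaged
geometry). Time is measured in minutes from the end of the injection.

## Neuraxis geometry and CSF pulsation descriptors

Cross-sections of the subarachnoid space are modelled as ellipses with
semi-axes a (lateral) and b (dorsoventral), partially occupied by spinal
tissue; the CSF-occupied area is πab(1 − tissue_fraction). Stations are
interpolated piecewise-linearly. The packaged station table is a
*synthetic* reconstruction: its anchor stations (CM, T2, L1, S3) match
published in vivo diameters and areas used for phantom validation, while
intermediate stations and tissue fractions are plausible interpolants —
treat it as a geometric scaffold, not as measured anatomy.

Pulsation descriptors derive from the pulsation frequency f (beats/min)
and stroke volume SV (mL/beat) under a sinusoidal volumetric waveform
Q(t) = Qa·sin(ωt) whose half-period displacement equals SV, so
Qa = SV·ω/2 with ω = 2πf/60 rad/s. At a reference CSF cross-section
A_ref (default: the C3 station, ≈1.24 cm²):

| quantity | definition | default inputs |
|---|---|---|
| Urms | Qa/(A_ref·√2), cm/s | — |
| Womersley α | (DH/2)·√(ω/ν) | DH = 0.5 cm, ν = 0.01 cm²/s (water) |
| Peclet Pe | Urms·DH/D0 | D0 = 1.938×10⁻⁶ cm²/min |
| amplitude ratio ε | Urms/(ω·L) | L = 65 cm |

With these definitions the physiological frequency range 40–127 bpm
spans α ≈ 5.1–9.1, placing the data just below the dispersion maximum of
the scale-analysis correlation (α ≈ 9.4) — the consistency check that
fixed this Womersley convention over the alternative √(DH²ω/ν).

## Finite-volume diffusion solver

∂C/∂t = D ∂²C/∂x² on a uniform cell-centred grid (default Δx = 0.1 cm),
zero-flux at both ends (closed dural sac: the observed tapering of
moment trajectories at the sacral end implies reflecting, not absorbing,
boundaries). Time integration is backward Euler with a direct
tridiagonal solve per step — unconditionally stable,
positivity-preserving, and mass-conservative to round-off (~1e−14
relative). Steps are subdivided so the diffusion number D·Δt/Δx² stays
≤ 50; for this spatially discretised operator the second moment grows at
exactly 2D per unit time regardless of Δt, so moment-based estimates are
not limited by temporal truncation error.

## Moments

First moments and left-sided second moments use trapezoidal quadrature
on the sampled positions; the cell containing the centroid is split with
linearly interpolated intensity. The left-sided moment of a symmetric
profile equals the full variance — the identity behind the MoM
convention D = slope/2. Frames whose caudal-side mass is below 10⁻⁶ of
the frame total are excluded (ill-conditioned moments). No background
subtraction is applied by default; an optional per-frame
constant-baseline subtraction (frame minimum) exists for records with a
uniform offset. The caudocranial velocity is the ordinary-least-squares
slope of M1 versus time, positive toward the head.

## Moment inversion (MIP) and method of moments (MoM)

MIP minimises Σᵢ (M2,left(tᵢ) − φ(D,tᵢ))² over D, with φ the left-sided
second moment of the finite-volume forward solution. Choices made where
the procedure was genuinely open:

* **Initial condition**: the first observed frame, interpolated to the
  solver grid and normalised to unit mass. Moments are scale-invariant,
  so the objective is insensitive to optical gain.
* **Search**: scalar minimisation over log₁₀ D (positivity by
  construction) with a bounded golden-section/parabolic method on an
  interval of ±2 decades around the MoM estimate (floored at 10⁻³
  cm²/min), tolerance 10⁻⁷ in log₁₀ D (~2×10⁻⁷ relative in D). A
  one-parameter problem needs no quasi-Newton machinery; on noise-free
  synthetic data the objective is unimodal over ±1 decade around truth.
* **Time alignment**: simulated moments are evaluated exactly at the
  observed frame times; no interpolation in time.
* **ROI**: observed and simulated moments use the same analysis window.

MoM fits M2,left = 2Dt by OLS; a negative slope flags the estimate as
non-physical. On wide domains with unreached boundaries the two agree to
well under 2%; once tracer piles against the sacral wall MoM is biased
low by tens of percent while MIP stays within 1% on noise-free records.

## Synthetic tracer generator

Phase 1 (injection): a uniform volumetric source over a 1 cm window
(a needle bolus occupies a finite canal segment) injects 2 mL over 60 s
while the field diffuses with D_true; concentrations carry units of
volume per cm so the spatial integral equals the injected volume. Phase
2 (observation): diffusion plus an optional constant caudocranial
advection (flux-form first-order upwind, CFL-substepped, closed ends),
sampled at 1-min frames for 10 min. With zero drift, phase 2 *is* the
diffusion solver output, bit for bit. Optical noise is multiplicative
Gaussian (σ_rel = 5% of the local value; uneven lighting) plus additive
Gaussian (σ_abs = 2% of the record's peak; sensor background), clipped
at zero. All randomness flows from a single integer seed.

Cohort generation draws D_true from the dimensional correlation at each
(f, SV) condition and the drift velocity from the frequency–CCV law
(0.29–0.44 cm/min over 40–127 bpm), optionally with log-normal scatter;
per-run seeds derive from the master seed via seed sequences.

What the generator does *not* emulate: radial concentration structure
(radial gradients are treated as negligible), within-cycle oscillatory
velocities (oscillation enters only through the effective D), video
artefacts beyond the two-term noise model, and any spatial variation of
D along the canal. Passing recovery tests on these records therefore
demonstrates the correctness of the inversion machinery under the stated
noise model — not the accuracy of the effective-diffusion description of
a real spine, which is an experimental question.

## Correlations

All logarithms are base 10. The three dispersion laws and the packaged
reference coefficients:

* dimensional: log D = a0 + a1·f + a2·f² + κ·log Urms, with
  a0 = −1.2220, a1 = 0.0067, a2 = −8.2069×10⁻⁵, κ = 0.9830;
* dimensionless: log ΔD = φ0 + φ1·α + φ2·α² + Κ·log Pe, with
  ΔD = (D − D0)/D0, φ0 = 0.4697, φ1 = −0.3977, φ2 = −1.2663, Κ = 0.9873;
* scale analysis: D/D0 = ε·λ(α), λ(α) = λ0 + λ1·α + λ2·α² with
  λ0 = −5477×10³, λ1 = 1580×10³, λ2 = −84.09×10³; fitted in the
  normalised form χ = (D/D0)/ε so plain OLS applies. The quadratic peaks
  at α = −λ1/(2λ2) ≈ 9.39.

**Units in the dimensional law.** The reference coefficients reproduce
dispersion coefficients of the observed magnitude (≈8 cm²/min at 72 bpm
and 1 mL/beat) only when Urms enters in cm/min; in cm/s they predict
values two orders too small. The package therefore evaluates and fits
the dimensional and CCV-vs-Urms laws with Urms in cm/min (the in-memory
`urms` fields remain cm/s). Fitting is by OLS on the linear-in-log form,
so recovery of coefficients from model-generated data is exact to
round-off regardless of the unit convention.

CCV laws are simple lines: CCV = 0.0018·f + 0.2144 (f in bpm) and
CCV = 0.0046·Urms + 0.2650 (Urms in cm/min), both in cm/min.

A numerical caveat: at physiological α ≈ 5–9 the dimensionless law's
quadratic makes λ(α) so negative that ΔD underflows double precision;
coefficient-recovery exercises for that law use a designed grid
(α ∈ [0.2, 1.1], Pe ∈ [3, 100]) where ΔD is representable.

## Six-compartment pharmacokinetic model

Spinal CSF (C1) is distributed along the canal:

    ∂C1/∂t = −u ∂C1/∂x + Deff ∂²C1/∂x² − k1·C1 − ṁ12 − ṁ15

with ṁ = σ(C_source − K·C_sink) transfer into spinal tissue (C2,
distributed, exchanging locally per axial position, no axial diffusion
of its own) and blood (C5, lumped). Cranial CSF (C3), cranial tissue
(C4) and a peripheral pool (C6) are lumped; the couplings C1↔C3 (at the
cranial boundary cell), C3↔C4, C3↔C5 and C5↔C6 use the same σ/K form and
default to zero, so by default the explicit spinal equations alone
define the behaviour. (One published form of the spinal-tissue flux
pairs C1 with the index-4 concentration while describing it as spinal
*tissue* absorption; this implementation takes the physically consistent
partner C2.) Injection-driven convection u = (dose rate)/(CSF area) acts
only during dose events, directed away from the dose site. First-order
loss k1 lumps binding/inactivation; K is the partition coefficient with
equilibrium convention C_source = K·C_sink.

Numerics: first-order operator splitting per substep — convection
(upwind, flux form) → implicit diffusion (the same kernel as the tracer
solver; with all other terms off the reduction to the plain solver is
exact, step for step) → reaction/transfer. Transfer updates move
identical amounts out of the source and into the sink: two-pool
exchanges use the exact closed-form decay of the partition
disequilibrium (unconditionally stable, equilibrium-preserving for any
Δt), the distributed↔lumped exchange uses backward Euler solved first
for the common sink concentration, and first-order losses use exact
exponentials accumulated into degradation/clearance ledgers. Closed
configurations conserve total mass to ~10⁻¹³ relative. Default internal
step: 0.5 min whenever reaction/transfer/dosing is active; `dt_max` lets
long dose-free stretches coarsen (e.g. 2-h steps for multi-month
schedules — a 90-day, three-dose run integrates in seconds on one CPU).
Default lumped volumes (100 mL cranial CSF/tissue, 5 L blood and
peripheral) are structural placeholders: order-of-magnitude physiology
for exercising the couplings, not fitted values.

## Problem sizes used in the shipped checks

Tests and the acceptance script run the bounded default grid (650 cells,
Δx = 0.1 cm, 11 frames), 10-seed noise ensembles, 20-trial MIP/MoM
comparisons, 12-experiment correlation cohorts and 10–30-step PK runs;
the full suite completes in well under a minute on one CPU. These sizes
were chosen as the smallest that make the statistical claims stable
across seeds.

## Known limitations

* The effective-diffusion description itself is an empirical input; the
  package quantifies and uses it but cannot validate it against a spine.
* With the full default noise model (multiplicative 5% *plus* additive
  2%-of-peak background over the whole domain), the clipped background
  inflates left-sided moments: MIP recovery error rises to ~7% median
  and repeat-spread to ~3%, versus ~0.2% under lighting noise alone.
  Real pipelines would background-correct frames before moment analysis;
  only a simple constant-baseline option is provided here.
* MoM and MIP estimate D only; drift is measured separately from M1 and
  never jointly estimated, and D is spatially uniform.
* The geometry table is a synthetic scaffold (see above); tissue
  fractions in particular are illustrative.
* Lumped-compartment parameters have no fitted physiological values in
  this package; PK results are structural/qualitative unless users
  supply their own rates and volumes.
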