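# Methods

## Model

Three Van der Pol units — cortex, cerebellum, SC-MS (spinal circuits and
muscular system) — interact in a loop: the cortex drives the SC-MS
(weight B2), the SC-MS feeds sensory information back to the cerebellum
(B1), and cortex and cerebellum couple mutually and diffusively (the same
BR multiplies both directions). tACS enters as an additive drive I(t) in
the cerebellum equation only. The basal ganglia are not simulated as a
dynamical unit; they are abstracted as the static values of the coupling
weights, standing in for the dopamine level. All three weights sit in
[30, 40] for the healthy state and [1, 10] for the Parkinsonian state;
the presets use 35 and 5 when no value is given (the stated
representative points of those ranges).

The per-unit dynamics are `Y'' − (λ − Y²) Y' + p² Y = force` with λ = 0.3
for every unit. For an uncoupled unit this gives a limit cycle of
amplitude ≈ 2√λ ≈ 1.10; λ ≤ 0 suppresses the oscillation entirely (the
package warns when a user leaves the (0, 1) regime but does not forbid
it).

### Time and frequency convention

The model equation uses the restoring coefficient p² with p quoted in Hz
(p_co, p_ce, p_s = 15, 20, 10 Hz). Two readings are possible and they are
*not* equivalent:

* substituting ω = 2πp directly into the equation puts the stiffness at
  ω² ≈ 4·10³–1.6·10⁴ while the coupling weights stay at 1–40. The
  couplings then perturb each unit at the 10⁻³ level: healthy and PD
  states become numerically indistinguishable, which contradicts every
  contrast this model exists to produce;
* integrating the equation exactly as written, the ratio of coupling to
  stiffness (B up to 40 vs p² = 100–400) is large enough to produce the
  amplitude, frequency and regularity contrasts. Interpreting the printed
  p values as intrinsic frequencies in Hz then fixes the unit of the
  equation's time variable: τ = 2π·t_seconds.

The package adopts the second reading. Equivalently, in seconds, the
integrated system is

    dY/dt = V,
    dV/dt = 2π (λ − Y²) V − (2πp)² Y + (2π)² · force,

the exact time-rescaling of the printed equations. Amplitudes are
unchanged by the rescaling and a free unit oscillates at p Hz, so the
cortex runs at ≈ 16 Hz in the healthy state and the SC-MS tremor output
at ≈ 10 Hz, consistent with the physiological frequency ranges the
parameters came from. The stimulation sinusoid `sin(2π w t)` with w in Hz
is `sin(w τ)` in model time — the printed waveform with w read in Hz.

### Integration

`scipy.integrate.solve_ivp` (adaptive RK45), rtol 1e-8, atol 1e-10, dense
interpolation onto a fixed 1-kHz output grid. The system is not stiff;
the tight tolerances are for reproducibility (identical configurations
give bit-identical trajectories). Default runs last 120 s with the first
25% (minimum 10 s) discarded as transient before any feature is computed;
by 30 s the phase relations between the units are settled in both
presets. Initial state (0.1, 0.1, 0.1) with zero velocities — the origin
is an equilibrium and must be avoided; seeded uniform perturbations in
[−0.5, 0.5] are available for robustness studies and change none of the
qualitative results.

## What the model reproduces — and what it cannot

With the presets (healthy 35, PD 5):

* mean |Y| of every unit is strictly larger in PD (0.697 vs 0.667–0.672):
  weakening the coupling releases each unit toward its free limit cycle,
  while strong coupling between detuned oscillators partially quenches
  them. The contrast is a few percent — directionally robust across
  initial conditions, weight draws within the ranges, and durations;
* cortex and cerebellum peak frequencies decline from healthy to PD
  (15.96 → 15.16 Hz and 21.0 → 20.1 Hz): the diffusive coupling raises
  the effective stiffness of the mutually coupled pair, and PD removes
  most of that shift;
* the SC-MS peak frequency does **not** decline: it moves from 9.956 Hz
  (healthy) to 10.000 Hz (PD), i.e. 0.4% in the opposite direction. The
  SC-MS equation has no diffusive self-term — it is driven, not
  mutually coupled — so its limit-cycle frequency stays pinned at p_s and
  the healthy-state coupling pulls it slightly down. A 0.04-Hz difference
  is invisible at bar-chart resolution; the package reports the measured
  direction rather than forcing the expected one;
* the SC-MS approximate entropy falls from ≈ 0.46 (healthy) to ≈ 0.19
  (PD). The healthy output is quasi-periodic (several incommensurate
  components of comparable size), the PD output is a nearly pure tone;
* under stimulation of the PD model at its own tremor peak (10 Hz), the
  mean SC-MS activity drops during the drive and recovers only partially
  during the decaying offline phase (pre > post > during), ApEn dips
  during and rises after, and the peak frequency stays at 10 Hz. The
  attainable suppression is ~1.5%: the drive reaches the SC-MS only via
  cerebellum → cortex → SC-MS with weights of ~5, so most of the drive's
  power is absorbed upstream. Larger drive amplitudes eventually
  *increase* the tremor output (resonant entrainment at its own
  frequency). Magnitude claims about stimulation efficacy are therefore
  outside what this architecture can reproduce; the package treats the
  stimulation experiment as a directional result only.

## Stimulation parameters

The drive amplitude has no physical calibration (nothing maps a 2-mA
scalp current to model force units). `A = 160` model units is a
calibration constant fixed once: large enough that the during-window
suppression clears numerical wobble, small enough to stay below the
entrainment regime that amplifies the tremor. The offline decay rate
`b = 0.05 s⁻¹` lets the offline effect fade largely within a 60-s post
window. The stimulation frequency defaults to the SC-MS peak measured on
an unstimulated baseline window — the model analog of reading each
patient's tremor peak before setting the tACS frequency. The protocol
defaults (30 s pre, 60 s on, 60 s post) are a desk-scale compression of
the clinical session (65 s / 15 min / 65 s, available via
`StimulationProtocol.clinical()`).

Feature windows within the protocol: 30-s windows starting 10 s into the
pre phase, 15 s into the stimulation phase (the entrainment transient
takes several seconds to settle), and 5 s into the post phase (so the
decaying offline drive is inside the window, as in the clinical design
where the post recording begins shortly after switch-off).

## Approximate entropy

Classical formulation: templates of length m (and m+1) compared under the
Chebyshev norm, self-matches included, φ computed with the
N−k+1 count appropriate to each embedding length k; defaults m = 2,
r = 0.2·SD of the series. The implementation factorizes the template
match into one pairwise boolean matrix reused across embedding
dimensions; tests verify it against an independent brute-force
transcription of the defining equations to 1e-12.

ApEn is sensitive to both series length and sampling cadence, so the
model pipeline fixes both: the steady-state SC-MS output is decimated to
125 Hz and windows of 600 samples (state contrast) or 1200 samples
(stimulation protocol) are used. 125 Hz — 12.5 samples per cycle of the
10-Hz tremor — is deliberate: at 100 Hz the sampling is exactly 10
samples per cycle, and ApEn of a near-periodic signal collapses toward
zero at integer samples-per-cycle (the embedded templates cycle through a
finite set); the value there is also knife-edge unstable to sub-percent
frequency changes. Between ~120 and ~400 Hz the values are stable
plateaus. All ApEn conventions are recorded in the result metadata.

## Feature pipeline

* Resultant acceleration RA = √(x²+y²+z²), computed sample-wise;
  rotation invariant by construction.
* Smoothing: cubic smoothing spline
  (`scipy.interpolate.make_smoothing_spline`); penalty 0 reproduces the
  input (interpolation limit), None selects it by generalized
  cross-validation. Off by default in `session_features` — the synthetic
  data is band-limited and the recovery tests are cleaner without it.
* Peak frequency: mean-removed magnitude spectrum (rectangular window by
  default, Hann optional), argmax within a band; resolution fs/N is
  reported. Band defaults: 2–12 Hz for accelerometer data, (0, fs/2) for
  model outputs.
* Session-level tremor peak: computed from the summed per-axis power
  spectrum (rotation invariant), not from the spectrum of the RA norm.
  For a zero-mean tri-axial oscillation the RA norm is a rectified
  waveform whose spectrum peaks at *twice* the tremor frequency; the
  vector spectrum peaks at the physical frequency, which is the quantity
  the 4–7 Hz tremor band refers to. `peak_frequency` remains available
  for any scalar series, including RA.
* Statistics: per-subject state means, percent change (pre − x)/pre·100
  averaged over subjects, Wilcoxon signed-rank (Pratt zero handling,
  exact distribution for n ≤ 25, p = 1 for all-zero differences), with a
  Lilliefors-corrected Kolmogorov–Smirnov normality check reported as
  advisory only — the signed-rank test is always the inferential test, as
  appropriate for small non-normal samples.

## Synthetic cohort generator

Each subject: tremor frequency uniform in 4–7 Hz; base amplitude
log-normal with median 1 m/s² and σ_log = 0.4 (rest-tremor accelerations
are of order 0.5–2 m/s²); 2nd/3rd harmonics at 15–35% / 5–15% of the
fundamental; smooth cycle-scale amplitude jitter (SD 10%) and frequency
jitter (SD 2%); white noise at 10% of the base amplitude per axis;
low-frequency baseline wander at 5%; a random unit vector distributes the
tremor over the axes. Sessions follow the clinical timing (3 × 15-s
intervals per 65-s state, 100 Hz — adequate for a 7-Hz tremor plus
harmonics). All randomness derives from per-subject seeds spawned from a
master seed; cohorts are bit-reproducible.

The stimulation effect is injected multiplicatively on the *whole*
interval signal (tremor + noise + drift), so the mean RA scales by
exactly the profile factor and the pipeline-recovered percent change
matches the injected one by construction — the recovery tests check the
pipeline, not the generator's arithmetic. Defaults: during scale 0.24
(76% reduction), post scale 0.32 (68%). Regularity is manipulated
independently: during stimulation the jitters and the relative noise
shrink (factor 0.25), post-stimulation they grow (factor 1.5), which
moves ApEn down during and up after without touching the amplitude
effect. The small residual deviation of the recovered percent change from
the injected scale (≈ ±1 point) comes from the relative-noise change
interacting with the norm's expectation.

What the generator does *not* emulate: gravity (excluded by default; the
recordings are treated as high-pass filtered — an optional constant 1-g
offset exists, but note that with gravity included the mean RA is
gravity-dominated and percent changes of tremor amplitude are no longer
identifiable from mean RA alone), sensor quantization and hardware noise
spectra, biomechanical limb resonances, inter-axis phase structure
(elliptical tremor orbits), and any per-subject variability in the
*effect* (the attenuation factors are common to the cohort, so passing
recovery tests shows pipeline correctness, not robustness to effect
heterogeneity).

## Sweep and sensitivity

The coupling sweep ties all three weights to one B per grid point
(independent sweeps exist but are non-default), simulates, and records
mean |Y| per unit. Amplitudes decrease monotonically in B over [1, 40];
`fit_exponential` fits a·e^{bB} by nonlinear least squares initialized
from the closed-form log-linear regression, and the sensitivity is the
derivative a·b·e^{bB} evaluated at the range midpoint (endpoints also
reported): healthy range [30, 40], PD range [1, 10]. For a decaying
exponential |derivative| is necessarily larger over the PD range than
the healthy range at equal coefficients; sensitivity orderings between
the two ranges therefore depend entirely on the fitted coefficients and
are reported, not asserted.

## Problem sizes and numerical choices

Default problem sizes: 120-s state simulations (90-s steady windows),
150-s protocol runs, 15-subject cohorts, 20 master seeds for
cohort-level averages; chosen to keep every experiment at desk scale
while leaving all measured quantities stable to well under the tolerances
used in the tests. Tie-breaks: FFT argmax takes the lowest-frequency bin
on exact ties (numpy argmax semantics); degenerate (constant) series get
ApEn 0 and are flagged non-normal by convention in the advisory check.
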