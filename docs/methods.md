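# Methods

## Spin model

The simulator represents each voxel's spin population in the extended
phase graph (EPG) basis: complex configuration states `F_k` (transverse)
and `Z_k` (longitudinal) indexed by an integer dephasing order `k`, where a
state of order `k` carries the spatial harmonic `exp(-i k Δk x)` along the
gradient axis and `Δk` is the dephasing-per-interval lattice unit.  Stored
arrays are `f_plus[k]`, `f_minus[k] = conj(F_{-k})` and `z[k]` for
`k = 0..k_max`; `f_minus[0] = conj(f_plus[0])` is an enforced invariant and
the hermitian symmetry `Z_{-k} = conj(Z_k)` makes the one-sided `z` array
complete.  The measurable voxel signal is `F_0`, the ensemble-mean
transverse magnetization.

Four elementary operators act on a state:

* **RF mixing** — the standard 3×3 per-order rotation for flip `α·b1` and
  phase `φ`; transmit-field (B1+) inhomogeneity enters the model only as
  the `b1` scale on nominal flip angles.  The mixing conserves
  `(|F⁺|² + |F⁻|²)/2 + |Z|²` per order to 1e-12 (tested).
* **Relaxation/recovery** — `E2 = exp(-τ/T2)` on transverse states,
  `E1 = exp(-τ/T1)` on longitudinal states, recovery `m0(1-E1)` into `Z_0`
  only (equilibrium magnetization is spatially uniform).
* **Diffusion** — per-order attenuation `exp(-D b)`.  For a transverse
  state traversing `k → k+s` under a constant gradient,
  `b = τ Δk² ((k + s/2)² + s²/12)` (the exact time integral of `k(t)²`,
  containing the 1/3 ramp term); a longitudinal state keeps its order and
  accrues `b = τ (kΔk)²`.  Verified against the closed-form isochromat
  value rather than trusted (tested to 1e-6).
* **Coherent flow** — plug motion at velocity `v` multiplies a transverse
  state traversing `k → k+s` by `exp(+i (k + s/2) Δk v τ)` (the mean order
  during the traversal) and `Z_k` by `exp(+i k Δk v τ)`: the spatial
  modulation pattern travels with the spins.  The sign convention is fixed
  by requiring exact agreement with the isochromat oracle.  The operator is
  pure phase (magnitudes untouched, tested); velocity *spread* is handled
  by batching an ensemble of simulations, never inside the operator.

Operator order within one interval is fixed and documented:
relax → diffuse → flow-phase → shift.  Units are SI internally (s, m,
rad/m); the public API uses ms, cm/s, mm²/s and rad/mm, converted at the
operator boundary.

`k_max` defaults to the total shift count of the whole protocol (capped at
4096), so default runs are truncation-free; when the cap binds, amplitude
shifted past `k_max` is dropped and monitored against a tolerance
(`warn`/`error`/`ignore` per call).  States above the cap in the capped
regime are many hundreds of lattice orders deep and strongly
relaxation/diffusion-attenuated.

All state arrays accept leading batch dimensions, so the 100-sample
velocity ensembles evolve as one vectorised pass; a batched run is
bit-identical to looping over its members (tested).

## Bloch oracle

An independent brute-force check: `n = 1000` isochromats on a
deterministic uniform grid spanning one unit-phase distance `L = 2π/Δk`
(the grid makes the DFT orthogonality exact, so the ensemble mean equals
the EPG order-0 amplitudes up to truncated orders).  Each isochromat is
rotated, relaxed and dephased event by event; moving spins advance and
accrue phase from their instantaneous position.  Oracle diffusion is an
analytic `exp(-bD)` on a globally tracked moment history, exact only when
RF pulses do not mix pathways between diffusion-weighted intervals, so
diffusion comparisons use prepared single-order states.  Random ≤50-event
sequences (static and flowing) agree with the EPG engine to better than
1e-3 M0; in practice the grid ensemble agrees to ~1e-15.

## Sequence

One repetition is DANTE → SPACE → recovery.  Defaults follow the
T2-weighted 7 T protocol: 300 DANTE pulses of 10°, 73 refocusing pulses,
equivalent TE 165 ms, TR 2.62 s, two repetitions for wall/CSF (signal
converged at the second; tested) and one for blood, which enters fresh
each TR.

**Preparation (DANTE).**  Pulse spacing, gradient moment and RF phase
scheme are not published for the reference protocol and are exposed as
parameters with calibrated defaults: spacing 1.4 ms, per-interval moment of
two lattice units with `Δk = 2.5π rad/mm`, alternating (0°/180°) RF phase.
The static-tissue behaviour is independent of `Δk` (no flow, no
diffusion), so the calibration splits cleanly: the (spacing, moment-units,
phase-scheme) triple was set on the stationary-wall behaviour
(repetition convergence, preparation-induced signal reduction and
point-spread-function broadening), and the lattice unit `Δk` on the
flow/diffusion physics (partial CSF suppression at 0.37 cm/s, the
diffusion-induced CSF signal reduction, and the sensitivity of the wall
signal to ~0.05 cm/s pulsation).  Alternating phase places the pulse
train's excitation comb half a period away from static spins, which is
what produces the published mid-readout magnetization dip — a lower signal
*and* a broader PSF — for prepared static tissue.

**Readout (SPACE).**  90° excitation, CPMG (90°-shifted) refocusing
phases, one configuration shift per half echo spacing, echoes recorded at
`F_0` at each inter-pulse midpoint.  Echo spacing defaults to
`2·TE_equiv / n_refocus` (4.521 ms) so linear k-ordering crosses the
k-space centre at the equivalent TE.  Readout intervals carry flow phase
and diffusion exactly like preparation intervals.

**Flip-angle design.**  The refocusing train is designed forward on a
static-tissue EPG recursion: at each echo the angle in (0°, 180°] is
solved so the simulated echo matches the prescribed target, then the state
is propagated.  The echo amplitude is *not* monotone in the angle once
longitudinal stores participate (it peaks mid-range and falls toward
180°), so the solver scans a 5° grid, brackets the smallest crossing —
storing excess magnetization longitudinally, as variable-flip-angle trains
are meant to — and declares infeasibility against the grid maximum,
naming the first infeasible echo.  By construction the design is
self-consistent: re-simulating static tissue reproduces the prescribed
curve to machine precision (asserted < 1 %).

**Prescribed evolution.**  The target family is a power law
`S(t) = A (1 + t/τ_c)^(-γ)` in units of the magnetization available at
excitation (defaults `A = 0.40`, `τ_c = 180 ms`, `γ = 1.5`).  Two
feasibility constraints of the static recursion shaped this choice: before
longitudinal storage builds up, the target cannot decay more slowly than
pure T2 per echo spacing, and later it cannot decay more slowly than the
sustainable pseudo-steady-state rate — which *lengthens* as the amplitude
drops, because magnetization increasingly waits along z between echoes.  A
power law has exactly this level-dependent rate (`(τ_c + t)/γ`, about T2
initially for the defaults); simple exponential-to-plateau targets violate
one of the two constraints at every scale and are rejected by the
designer.  `A` is calibrated so the full protocol reproduces the
unprepared stationary-wall signal level of 0.13 M0.

**Recovery.**  `TR − durations`, applied as one relaxation interval
carrying a single configuration shift (a mild spoiler); no explicit
spoiler gradient beyond that.

## Physiology

* **Intravoxel velocity spread** — `n = 100` draws from
  `Normal(v̄, (0.1 v̄)²)`; negative draws are kept (they flip the phase
  direction).  The ensemble's complex-mean echo train is the voxel signal;
  magnitudes are taken afterwards.  Complex averaging is the physical
  choice for sub-voxel populations and was kept after evaluating
  magnitude-averaging, which moved the combined-CSF comparison away from
  its reference value.
* **Pulsatility** — periodic waveforms at 60 bpm with a uniform random
  start phase per ensemble member (acquisitions are not cardiac gated).
  CSF- and wall-like waveforms are two-harmonic oscillations with exactly
  zero net displacement per cycle, rescaled to mean |v| = 0.37 and
  0.054 cm/s; the blood waveform is a systolic-peaked positive curve with
  mean 24 cm/s and a 16.5 cm/s diastolic floor.  These are parametric
  stand-ins reproducing stated summary properties, not digitised
  physiological recordings — results that depend on waveform *shape* are
  approximate.
* **Direction** — only the velocity component along the gradient dephases
  spins (`cos β` projection).  CSF, whose direction varies across the
  brain, uses the solid-angle mean angle over a hemisphere,
  `⟨β⟩ = 1 rad = 57.3°` (closed form; cross-checked by quadrature and
  Monte Carlo).  Slow wall pulsation is modelled along the gradient
  (`β = 0`); direction effects on the wall are deliberately not modelled.
  Blood additionally carries `readout_beta = 85°`, the nearly
  perpendicular angle between carotid inflow and the readout gradient —
  the two gradient axes differ in reality, which a single-axis lattice
  cannot otherwise express.
* **Trajectory and B1+** — blood traverses a synthetic 25 cm
  coronal-plane path with a siphon-like distal bend, anchored to reach the
  voxel at the centre of the echo train; its tangent angle and local B1+
  (rising 0.35 → 0.97 from neck to head with seeded smooth ripple) become
  functions of time at the 24 cm/s mean speed.  Wall/CSF take a constant
  B1+ scale.

## Signal metrics

Echoes are reordered into k-space (linear ordering by default, centre at
the equivalent-TE echo), zero-padded ×8 and inverse-Fourier transformed.
Normalisation makes a flat train of value `c` give PSF amplitude `c`.  The
scalar "signal" of a run is the PSF amplitude of the ensemble-average
train of the final repetition (the k-centre echo magnitude is reported
alongside); FWHM is measured by linear interpolation on the padded
profile, in voxel units.  Contrast is `PD_a S_a − PD_b S_b` with
`PD_wall = 0.72`.  The relative signal `100 · S / S_unprepared-static`
versus mean wall velocity is strictly decreasing over [0, 0.12] cm/s and
is inverted by monotone (PCHIP) interpolation to estimate a wall velocity
from an observed relative signal; a simulated 0.054 cm/s wall is recovered
within 10 % (tested, independent seed).

## Problem sizes

Default study conditions are used throughout the tests and the acceptance
script: 100-sample ensembles, 300-pulse preparation, 73-echo readout, two
repetitions (seven for the convergence analyses), 1000-isochromat oracle
ensembles.  The velocity-inversion curve uses seven velocities in
[0, 0.12] cm/s at 100 samples each.

## Known limitations

* The preparation timing/gradient/phase defaults and the prescribed
  readout curve are calibrated stand-ins for unpublished protocol
  internals; quantities tied to them inherit that uncertainty even where
  the packaged defaults reproduce the reference values.
* The repetition-to-repetition *drop* of the constant-velocity CSF signal
  simulates at 50–70 % in this framework, much larger than the ~25 %
  reference value.  Structurally, after the 90° excitation consumes the
  longitudinal pool, end-of-train magnetization survives as spatially
  modulated `Z_k (k>0)` states that cannot feed uniform-Mz recovery, so
  the second repetition's pool is bounded by T1 recovery of a T1 ≈ 4 s
  tissue over ~1.9 s.  The converged (second-repetition-onward) CSF level,
  which all contrast results use, is stable to < 1 %.
* The combined physiological blood model suppresses more strongly
  (~65–80 % below the basic model) than the ~27 % reference: with a 10 %
  spread at 24 cm/s, every flow-phase-carrying pathway decoheres
  completely under the synthetic trajectory/B1 stand-ins.  Directionally
  correct, magnitude overstated.
* Beyond ~0.12 cm/s mean wall velocity the 100-sample complex mean sits at
  its decoherence noise floor (few % relative signal), so the
  velocity-inversion curve is built over [0, 0.12] cm/s — comfortably
  containing the physiological estimates (~0.05 cm/s).
* Passing tests demonstrate consistency of the spin physics and the
  implemented physiological mechanisms, not fidelity to any individual
  subject: real waveform shapes, 3-D CSF flow, slab profiles,
  magnetization transfer and k-space sampling beyond a 1-D ordering are
  out of scope.
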