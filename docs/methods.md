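# Methods

## Sensor model

The simulator represents a photochromic Ca²⁺ biosensor by an effective
four-state scheme: the protein is Ca²⁺-bound (*sat*, fraction θ) or
Ca²⁺-free (*apo*, fraction 1−θ), and within each occupancy it is in a
fluorescent on-state or a dark off-state. Occupancy follows a Hill law,
θ(Ca) = Ca^h / (K_d^h + Ca^h), with K_d = `kd_occupancy` and
h = `hill_h`. Ca²⁺ exchange is treated as fast relative to a camera frame:
only the mixing weight θ follows the Ca²⁺ trajectory, while each
subpopulation carries its own on-state fraction n_sat(t), n_apo(t).

Light-driven switching is first order with rates proportional to the
applied intensity. During an illumination event of intensity I the
on-fraction of a subpopulation relaxes analytically,

    n(t) = n_eq + (n₀ − n_eq) · exp(−(k_on + k_off) · I · t),
    n_eq = k_on / (k_on + k_off),

and in the dark it recovers thermally toward the fully-on state with time
constant `tau_thermal_*`. Because the per-event problem is linear with
constant coefficients, every event is propagated in closed form — there is
no ODE solver, no step-size or tolerance question, and simulations are
exact to floating point. Two properties that the quantification strategy
rests on follow directly: the off-switching plateau n_eq is independent of
intensity, and the relaxation time scales as 1/I.

Recorded fluorescence at a camera frame (timestamped at the start of the
exposure) is the occupancy-weighted mixture

    F = θ·B_sat·(n_sat + r(1−n_sat)) + (1−θ)·B_apo·(n_apo + r(1−n_apo)),

scaled per cell by its expression factor and by `fatigue_retention` to the
power of completed photochromism cycles, plus background and optional
noise. r is the residual off-state brightness (0 by default: the measured
plateau is attributed to the switching equilibrium, not to off-state
emission).

Two empirical phenomena are modelled as single multiplicative factors
because their mechanism is not resolved by the data the model is built
from, and the package makes no mechanistic claim about them:

- **Deviant first cycle** — during the first photochromism cycle every
  per-event switching amplitude is scaled by `first_cycle_factor`
  (default 1.15). Analyses discard the first cycle (`n_discard = 1`).
- **Post-cycle dip** — the first intermittent frame after a completed
  photochromism cycle is scaled by `post_cycle_dip_factor` (default
  0.95), standing in for a transient non-fluorescent intermediate that has
  not fully relaxed by the next frame. The dip is scoped to intermittent
  frames (where it is observed and repaired); frames inside a cycle are
  not dipped.

## Default parameter set (GCaMP6s-Q)

The packaged defaults describe the photochromic GCaMP6s-Q sensor under the
default instrument protocol: one 100 ms violet pulse at 59.3 mW followed
by ten 100 ms cyan frames at 46.7 mW, repeated every 2 s (one acquisition
block = 1.1 s of illumination). Rate coefficients are not directly
measurable, so they are back-calculated from observable anchors:

| anchor | value | role |
| --- | --- | --- |
| off-switching τ (sat / apo) | 0.18 s / 0.50 s at 46.7 mW | fixes k_on + k_off per form |
| second-cycle contrast (sat / apo) | 0.86 / 0.0071 | fixes the on/off split (n_eq) per form |
| fluorescence titration | K_d 266 nM, h 2.1 | occupancy parameters |
| contrast titration | K_d 51 nM | fixes the apo/sat brightness ratio |
| fatigue | 50% F₀ after 1000 cycles | `fatigue_retention` = 0.5^(1/1000) |

The second-cycle contrast inversion is closed form: with the per-event
propagation above, the deficit 1−n is linear through cycle 1 (with the
first-cycle amplitude factor applied per event), the dark gap, and the
violet pulse, so the equilibrium fraction that reproduces a given measured
contrast can be solved exactly (`peaq.params._cycle2_equilibrium`).

The shift between the two titrations is emergent rather than imposed. For
a mixture whose per-state read-out is Ca-independent, both titrations are
exactly Hill-shaped: the fluorescence curve inherits (K_d, h) of the
occupancy, while the contrast curve is brightness-weighted and appears at

    K_d(contrast) = K_d(occupancy) · (b/a)^(1/h),

where b/a is the observed apo/sat brightness ratio. The default apo
brightness is therefore set so that b/a = (51/266)^2.1 ≈ 0.031, which
simultaneously reproduces the contrast K_d of 51 nM and a Ca²⁺ sensitivity
(F_sat − F_apo)/F_sat of 0.97.

Choices that are *not* back-calculated from measurements, and are flagged
as packaged values: thermal recovery constants (300 s sat / 600 s apo; the
source measurements do not pin them down unambiguously), the violet-pulse
on-switching time constant (0.01 s, i.e. recovery is complete within one
100 ms pulse), the violet inertness of the apo form (its violet
off-switching rate defaults to 0; the apo form of this sensor is
essentially photochromism-silent), the sat on-state brightness scale
(100 counts per unit probe), and the EGTA dissociation constant of the
titration ladder (150 nM for the kit buffer conditions, pH 7.2, 100 mM
KCl). The ladder itself follows the reciprocal-dilution law
Ca_free = K_EGTA · R/(1−R), with the first point exactly 0 and the last
pinned to the saturating buffer (39 μM by default, 11 points).

## Noise and nuisance processes

Measurement noise is Poisson shot noise at a configurable photon-per-count
gain (default 1.0) plus Gaussian read noise (default σ = 1 count), clipped
at zero — the simplest model that reproduces brightness-dependent
variability. Background (default 4 counts, the empty-region signal level)
is added to every cell frame and recorded separately as the background
trace that `background_correct` subtracts. Per-cell expression scales are
log-normal when a CV is configured. All randomness derives from one master
seed via spawned, per-cell streams; identical inputs give bit-identical
output.

Stylized Ca²⁺ trajectories are provided for constant baths, titration step
ladders, and agonist-evoked oscillations (rectangular spikes on a
baseline, default 60 nM baseline / 1000 nM peak / 30 s period, with a
per-spike amplitude decay). These are plausibility defaults for exercising
the pipeline, not measured dynamics.

## Analysis pipeline

- **Contrast** is (F₀ − F_end)/F₀ with F₀ the first and F_end the last
  cyan frame of a cycle; the first cycle is discarded by default. In
  `exponential_plateau` mode F_end is replaced by the plateau of a
  least-squares fit of amplitude·exp(−t/τ) + plateau over the first 10
  frames (deterministic initialization: plateau from the last point,
  amplitude from first−last, τ from the interpolated 1/e crossing). This
  makes the contrast insensitive to whether the applied dose actually
  reached the plateau, at the price of a fit; switching F_end mode changes
  the effective calibration, so the calibration fingerprint (protocol
  settings) is stored with every curve and quantification refuses
  mismatched fingerprints unless overridden.
- **Hill fitting** minimizes unweighted squared residuals with a
  deterministic, scale-free initialization (asymptote from the largest
  concentration, K_d from the half-range crossing, h = 2) and bounds
  h ∈ [0.2, 10], K_d within a factor 100 of the sampled nonzero
  concentrations. Standard errors come from the Gauss–Newton curvature.
- **Working range**: inversions whose response falls in the extreme
  `working_fraction` (default 5%) bands of the calibration are flagged and
  clipped to the working-range edge concentration; the unclipped value is
  kept alongside. The 5% default is a judgement call exposed as a
  parameter. Cells whose peak F₀ is below the brightness gate (default
  30 counts) are excluded entirely.
- **Intermittent quantification** computes A_i = F₀/F_T(Ca_i) at each
  calibration cycle, fits a straight line to the A_i with per-point
  standard deviation 1/F₀ (variance weights F₀²), and inverts each
  repaired intermittent frame through Ca = F_T⁻¹(F₀/A(t)). Calibration
  points whose contrast is outside the working range are excluded from
  the trend (their inferred Ca, hence F_T, is unreliable). The dip repair
  replaces each first post-cycle frame by the mean of its neighbours *in
  the F₀ series* (cycle F₀ frames and intermittent frames); interpolating
  in the raw frame sequence would average against a fully off-switched
  frame. Light-dose saving is 1 − (C + N·c)/((1+N)·C) for cyan, with C
  and c the per-cycle and per-frame cyan doses; violet is reported
  separately and not asserted.

## Known limitations

- The scale-factor relation F₀ = A·F_T(Ca) is exact only when the apo
  form is non-fluorescent. With the default 3% apo/sat brightness ratio,
  an A calibrated at near-resting occupancy overestimates the scale for
  high-occupancy frames (and vice versa). The brightness weighting of the
  trend fit mitigates this — bright, high-occupancy calibration points
  dominate — but accurate intermittent estimates require calibration
  cycles that sample the concentration range of interest. Relatedly, the
  mismatch between the contrast K_d (51 nM) and fluorescence K_d (266 nM)
  narrows the window where both read-outs are simultaneously in range
  (about 65–207 nM at the 5% working fraction); the package surfaces both
  working ranges but does not attempt to correct for the mismatch.
- The trend model for A(t) is a straight line only; it tracks slow
  monotone drift (bleaching, expression changes) but not fast probe
  dynamics.
- The two subpopulations keep separate photochromic states; molecules
  exchanging occupancy mid-cycle are not tracked individually. This is a
  good approximation when Ca²⁺ is quasi-static within one cycle and
  consistent with measuring calibrations and experiments under identical
  protocols, but cycles that straddle a fast concentration change will be
  distorted (as any finite-duration acquisition is).
- Passing tests on simulated traces demonstrate the internal consistency
  of the pipeline under the stated model — they do not validate the model
  against real microscope data, which additionally shows cell motion,
  focus drift, heterogeneous backgrounds, and pH sensitivity that the
  generator does not emulate.

## Problem sizes used in tests and the benchmark script

Simulated checks use single cells with 2–12 photochromism cycles (plus 8
intermittent frames per gap for intermittent scenarios), 11-point
titrations, and one 1000-cycle fatigue series; the noisy-calibration bias
check uses 200 replicate 11-point fits. These sizes keep every result
deterministic and the whole suite fast while matching the protocol
dimensions the defaults were calibrated for.
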