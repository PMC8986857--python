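# peaq

Absolute quantification of biosensor activity from photochromic
fluorescence traces.

Single-fluorophore biosensors such as the GCaMP family report Ca²⁺ as a
fluorescence intensity, which confounds the analyte concentration with
probe expression and illumination intensity. Photochromic sensor variants
offer a way out: cyan light drives the fluorophore toward a non-fluorescent
state and violet light recovers it, and the *extent* of that switching
depends on Ca²⁺ occupancy. The photochromism contrast

    (ΔF/F₀)hv = (F₀ − F_end) / F₀

measured over one off-switching cycle is a ratiometric quantity —
independent of probe concentration, photobleaching, and (at the switching
equilibrium) of the absolute excitation intensity — and can be inverted
through an in vitro titration curve to yield the absolute Ca²⁺
concentration. This package implements that strategy (photochromism-enabled
absolute quantification, PEAQ) and its fast variant (iPEAQ), in which
occasional photochromism cycles calibrate a per-cell brightness scale
factor `A` so that cheap single-frame fluorescence acquisitions in between
can also be converted to absolute concentrations, saving most of the cyan
light dose.

The package provides, for users who analyse or prototype such experiments:

- **`peaq.simulate`** — a forward simulator of per-cell fluorescence traces
  under programmed illumination schedules: four-state kinetics (Ca-bound
  *sat* / Ca-free *apo* × spectroscopic on/off), intensity-proportional
  switching with an equilibrium plateau, thermal recovery in the dark,
  per-cycle switching fatigue, a deviant first cycle, the transient
  post-cycle dip, expression variability, background, and shot/read noise.
- **`peaq.calibration`** — Hill-model titration fitting
  `f(Ca) = F_diff·[1 − Ca^h/(K_d^h + Ca^h)] + F_max`, closed-form
  inversion, [0, 1] normalization (the `F_T` form), and working-range
  policy (the extreme 5% response bands are flagged unreliable).
- **`peaq.quantify`** — background correction, cycle segmentation,
  contrast computation with optional exponential-plateau extrapolation of
  `F_end`, and calibration lookup with range flags.
- **`peaq.intermittent`** — scale factors `A = F₀ / F_T(Ca)`,
  brightness-weighted linear drift modelling of `A(t)`, inversion of
  intermittent frames via `Ca = F_T⁻¹(F₀/A)`, dip repair, and light-dose
  accounting.
- **`peaq.io` / `peaq.cli`** — CSV/JSON artifacts with instrument-settings
  fingerprints, and a `peaq` command with `simulate` / `calibrate` /
  `quantify` / `ipeaq` subcommands.

## Worked example

Simulate a HeLa-like cell held at 150 nM free Ca²⁺ under the default
protocol (one photochromism cycle every 2 s: a 100 ms violet pulse at
59.3 mW, then ten 100 ms cyan frames at 46.7 mW), calibrate from a
simulated 11-point titration, and quantify:

```sh
$ cat run.yaml
seed: 7
protocol:
  n_cycles: 4
trajectory:
  kind: constant
  ca_nM: 150
analysis:
  brightness_gate: 10

$ peaq simulate  --config run.yaml --output-dir sim
wrote sim/traces.csv (1 cells, 40 frames)
$ peaq calibrate --config run.yaml --output-dir cal
wrote cal/calibration_contrast.json (kd=51 nM, h=2.1)
wrote cal/calibration_fluorescence.json (kd=266 nM, h=2.1)
wrote cal/calibration_fluorescence_normalized.json (kd=266 nM, h=2.1)
$ peaq quantify --traces sim/traces.csv --schedule sim/schedule.csv \
    --calibration cal/calibration_contrast.json \
    --config run.yaml --output-dir quant
wrote quant/quantification.csv (3 points, 0 flagged)
$ head -4 quant/quantification.csv
cell_id,time_s,ca_nM,ca_raw_nM,flag,method
cell_000,2.0999999999999996,150.0,150.0,ok,peaq
cell_000,4.1,149.96333975824908,149.96333975824908,ok,peaq
cell_000,6.099999999999996,149.9583811088431,149.9583811088431,ok,peaq
```

The two calibrations differ deliberately: the fluorescence titration
reflects occupancy directly (K_d 266 nM for the default GCaMP6s-Q
parameter set), while the contrast titration is brightness-weighted toward
the bright Ca-bound form and therefore shifts to an apparent K_d of 51 nM.
The first cycle of each trace is systematically deviant and discarded
(`n_discard: 1`); the three remaining cycles each yield an absolute
concentration, recovering the ground truth within 0.03%. Points whose
contrast falls in the extreme 5% bands of the calibration would be written
with `flag` set to `below_range`/`above_range` and clipped to the
working-range edge (the unclipped inversion is kept in `ca_raw_nM`).

For iPEAQ, add `n_intermittent: 8` to the protocol block and run
`peaq ipeaq` with both calibrations; the dose report then shows
`cyan_saved_fraction: 0.80` — alternating each 10-frame photochromism cycle
with 8 single-frame acquisitions saves 80% of the cyan light dose.

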