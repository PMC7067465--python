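# Methods

## Model

The circuit couples a three-population thalamic module (TCR relay, IN
interneurons, TRN reticular nucleus) to a four-population cortical
module (PY pyramidal cells, eIN excitatory interneurons, sIN/fIN slow
and fast inhibitory interneurons). Two structural features distinguish
it from simpler thalamocortical mass models: a cortical disinhibition
pathway (fIN→sIN, strength `C_lfi`) and full relay projections from TCR
onto all four cortical populations (`C_pte`, `C_xte`, `C_lte`,
`C_fte`).

Every population is a standard second-order synaptic filter
(`ẋ₁ = x₂`, `ẋ₂ = (H/τ)u − (2/τ)x₂ − x₁/τ²`, impulse response
`(H/τ) t e^{−t/τ}`). The two input blocks (retinal,
cortico-cortical) are driven directly by their extrinsic rates; the
seven interior blocks are driven by `S(V)`, the shared sigmoid
(`v = 0.56 /mV`, `e₀ = 2.5 /s`, `s₀ = 6 mV`, output bounded by
`2e₀ = 5 spikes/s`) applied to the signed connectivity-weighted sum of
presynaptic PSP outputs. Membrane potentials use only the `x₁`
components; inhibitory terms enter with a minus sign.

Module-specific constants: the retinal and TCR blocks use the thalamic
excitatory pair (`He = 3.25 mV`, `τe = 10 ms`); the cortico-cortical,
PY and eIN blocks the cortical pair (`2.7 mV`, `25 ms`); IN and TRN the
thalamic inhibitory pair (`22 mV`, `25 ms`); sIN (`4.5 mV`, `50 ms`)
and fIN (`39 mV`, `3 ms`) the cortical slow/fast inhibitory kinetics.
Each block belongs anatomically to exactly one module, which fixes the
assignment. All internal computation is in SI units (s, mV, spikes/s);
the parameter file uses milliseconds for time constants and is
converted on load, which avoids mixed-unit bugs in the `1/τ²` terms.

## Numerics

* **Integrator**: forward Euler, the conventional choice for this model
  family, with the drive sample held constant within each step.
  Default `dt = 0.1 ms`; the fastest time constant (`τ_if = 3 ms`)
  then spans 30 steps. A guard rejects
  `dt ≥ min(τ_if, τe_thal)/5`. The compiled kernel is tested against a
  pure-NumPy reference right-hand side and against a high-accuracy
  LSODA solution.
* **Initial conditions**: all 18 states zero. The initial transient
  (default 5 s of a 20 s run) is discarded before any analysis.
* **Divergence guard**: any |state| above 10⁶ mV aborts with the step
  index and the parameter set; this is orders of magnitude above the
  physiological scale and cleanly separates instability from
  oscillation.
* **Noise**: "Gaussian white noise with mean μ and variance φ" is read
  as per-step sampling with variance φ. Because that convention makes
  the effective drive power depend on dt, an optional
  spectral-density mode (`noise_as_density=True`, variance φ/dt) is
  provided; all shipped analyses use the per-step reading.
* **Seeding**: every stochastic quantity derives from one integer seed
  through `numpy` `SeedSequence`; ensemble realization k and sweep cell
  (i, k) get deterministic child seeds, so single members are
  reproducible in isolation and results are independent of execution
  order. Identical seed and config give bitwise-identical output.

## Spectral pipeline

Per realization, the post-transient thalamic output is decimated to
1 kHz (anti-aliased, ample margin above the 50 Hz analysis edge),
band-pass filtered with an order-10 Butterworth design applied
forward–backward (zero phase, so the peak location is not biased), and
Welch-transformed with a Hamming window, 2 s segments and 50% overlap
(0.5 Hz resolution, ≥ 14 averaged segments at the default duration).
Ensemble averaging acts on the PSD curves, not the raw signals:
realizations are phase-incoherent, so signal averaging would cancel the
oscillation itself. The alpha-band peak is the maximum of the averaged
PSD on 7.5–13.5 Hz.

The steep-decline detector for sweep curves smooths with a 3-point
moving average, finds the maximum-|slope| point, and extends the
segment while the slope magnitude stays above 20% of that maximum.
A segment counts as significant only if the drop across it exceeds 30%
of the curve's range *and* the high side is at least twice the low side
— the transitions of interest change power by an order of magnitude,
and the ratio test keeps noise wiggles on a flat curve from being
reported as a decline. These thresholds were fixed at design time.

## Bifurcation analysis

Attractors are classified from simulation, matching how this model
family is analysed in practice: a fresh zero-state, noise-free run
(drives frozen at μ_r, μ_c — the deterministic skeleton) per parameter
value, extrema of the last 50% of the post-transient output by
discrete-derivative sign change, and the label "point" iff the
peak-to-peak amplitude is below 10⁻⁴ mV (far below mV-scale cycles,
far above double-precision noise). Reported maxima/minima are medians
of the detected local extrema, robust to residual transients. A label
change along a sweep is refined by bisection on the label (default
bracket width 0.05). Fresh initial states per value deliberately avoid
continuation, so no hysteresis assumptions are imported; the
zero-crossing cycle-frequency estimate is independent of the Welch
pipeline and serves as its oracle.

## What the default parameter set actually does

An honest account of the shipped defaults, established numerically (and
cross-checked with an independent adaptive integrator and with
equilibrium/eigenvalue analysis):

* From the zero state the deterministic skeleton converges to a unique
  stable equilibrium; multi-start root finding locates no other
  equilibrium, and random-initial-state probes find no coexisting
  attractor. Its dominant eigenmode is a damped ~5 Hz resonance, so
  under stochastic drive the PSD mass sits below the alpha band and the
  7.5–13.5 Hz "peak" lies on that resonance's shoulder.
* The one robust attractor transition inside the standard sweep ranges
  is carried by the disinhibition strength `C_lfi`: a Hopf point at
  ≈ 14.6 (bifurcation conditions: 20 s runs, dt = 0.1 ms). The cycle
  born there is a cortical sIN/fIN oscillation with fundamental
  ≈ 17 Hz (beta), peak-to-peak ≈ 4 mV in `V_tcr`; across this
  transition the spectral sweep curve shows the expected two-plateau
  shape with an order-of-magnitude power jump, and the spectral decline
  onset agrees with the located Hopf point within grid resolution.
* Sweeps of `C_fte` (25–45) and `C_pxe` (98–118) cross no attractor
  transition: increasing `C_fte` in fact *damps* the dominant mode
  (the fIN→PY inhibition outweighs the disinhibitory loop at this
  operating point, because TCR and fIN sit low on the sigmoid).
  `C_tii` sweeps are likewise transition-free; at the very bottom of
  the 5.45–17.45 range the weakly damped focus decays so slowly that a
  20 s run can still exceed the 10⁻⁴ mV amplitude tolerance, which the
  sweep reports as a (spurious) label change at the range edge —
  lengthening the run resolves it.

Passing tests therefore demonstrate the correctness of the machinery —
the integrator against closed-form and adaptive-solver oracles, the
filters and Welch estimator against analytic signals, the
bifurcation/bisection logic on the `C_lfi` transition, and full seeded
reproducibility — not that every connectivity pathway exhibits an
alpha-band Hopf bifurcation at these defaults. The simulated drives are
white and stationary; real EEG background activity is neither, so
spectral magnitudes should be read comparatively, not as μV-calibrated
predictions.

## Limitations

* Forward Euler is first-order; the default step is validated by
  halving (settled output changes < 10⁻³ mV, cycle frequency < 1%),
  but stiff parameter regions (very small τ) need a smaller dt.
* Attractor classification from a finite run mislabels near-threshold
  points where transients outlive the simulation; the bisection
  tolerance should be read together with the run length.
* No spatially extended cortex, no conductance-based dynamics, no
  fitting to recorded EEG; sub- vs supercritical character of located
  Hopf points is not assessed beyond the label change.
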