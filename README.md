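# tctalpha

A simulator and analysis toolkit for a thalamo-cortico-thalamic (TCT)
neural mass model of the EEG alpha rhythm, built to study how loss of
synaptic connectivity — the hallmark neuropathology of Alzheimer's
disease — reshapes the power spectrum of the thalamic output.

It is aimed at computational neuroscientists who want a reproducible,
scriptable implementation of the full pipeline: stochastic simulation of
the circuit, the band-pass/Welch spectral analysis used on its output,
and the nonlinear-dynamics machinery (bifurcation diagrams, Hopf-point
bisection, phase portraits) that explains spectral changes in terms of
attractor transitions.

## The model

Nine interacting neuronal populations, each lumped into a second-order
synaptic filter with gain `H` (mV) and time constant `τ` (s):

    ẋ₁ = x₂
    ẋ₂ = (H/τ) u(t) − (2/τ) x₂ − (1/τ²) x₁

The thalamic module contains the thalamo-cortical relay (TCR),
inhibitory interneurons (IN) and the reticular nucleus (TRN); the
cortical module contains pyramidal cells (PY), excitatory interneurons
(eIN) and slow/fast inhibitory interneurons (sIN, fIN), including a
disinhibitory fIN→sIN pathway and full TCR relay projections onto all
four cortical populations. Two extrinsic Gaussian drives enter the
circuit: retinal input (mean μ_r, variance φ_r) and cortico-cortical
input (μ_c, φ_c). For the interior populations the filter input is the
sigmoid-transformed membrane potential,

    S(V) = 2e₀ / (1 + exp(v (s₀ − V))),    V = Σ ± C_xyz · x₁,presyn

where the 23 dimensionless constants `C_xyz` (named target–source–type,
e.g. `C_fte` = TCR→fIN excitation) set the synaptic connection
strengths. The model output is `V_tcr`, the TCR membrane potential.
All default constants ship in `src/tctalpha/data/defaults.yml` and can
be overridden from a flat YAML file or per-call.

Analyses provided:

* **Simulation** — seeded forward-Euler integration (default
  dt = 0.1 ms, 20 s, zero initial state), deterministic per-realization
  child seeds for ensembles, divergence and step-size guards.
* **Spectral pipeline** — decimation to 1 kHz, zero-phase order-10
  Butterworth band-pass (1–50 Hz), Welch PSD (Hamming window, 2 s
  segments, 50% overlap), ensemble-averaged PSD curves, and sweeps of
  peak alpha-band (7.5–13.5 Hz) power versus any parameter, with a
  detector for the steep-decline segment of a two-plateau sweep curve.
* **Dynamics** — steady-state extrema of the noise-free output,
  point-attractor vs limit-cycle classification, bifurcation diagrams
  over any connectivity constant, bisection refinement of the Hopf
  point, phase portraits, and a zero-crossing cycle-frequency oracle.

## Worked example

The strongest attractor transition in this parameter set is carried by
the cortical disinhibition pathway `C_lfi` (fIN→sIN). Locating its
Hopf point by bisection from the shell:

```
$ tctalpha hopf --param C_lfi --lo 10 --hi 20 --fast
critical C_lfi = 14.5508
```

Below this value the circuit settles to a point attractor; above it a
limit cycle appears and the spectral power of the thalamic output jumps
by an order of magnitude. The same computation from Python, just above
the transition:

```python
import tctalpha as ta

p, C = ta.default_parameters(), ta.default_connectivity()
cfg = ta.SimulationConfig(duration=20.0, transient=5.0, seed=1, n_realizations=10)

trajs = ta.run_ensemble(p, C.replace(C_lfi=16.0), cfg)
res = ta.alpha_peak_of_run(trajs, ta.SpectralConfig())
print(f"peak alpha-band power: {res.alpha_peak:.3e} mV^2/Hz at {res.alpha_peak_freq:.2f} Hz")

nf = cfg.replace(noise_on=False, n_realizations=1)
traj = ta.euler_integrate(p, C.replace(C_lfi=16.0), nf)
ex = ta.steady_extrema(traj)
print(f"attractor: {ta.classify_attractor(ex)}, amplitude {ex.amplitude:.3f} mV,"
      f" fundamental {ta.cycle_frequency(traj):.2f} Hz")
```

prints

```
peak alpha-band power: 4.724e-05 mV^2/Hz at 13.50 Hz
attractor: limit_cycle, amplitude 3.905 mV, fundamental 17.37 Hz
```

i.e. a ~3.9 mV peak-to-peak limit cycle whose fundamental sits in the
beta range, with the alpha-band PSD maximum at the 13.5 Hz band edge —
see `docs/methods.md` for a candid account of which oscillatory regimes
this parameter set does and does not produce.

Figure-level experiments (sweep tables, bifurcation diagrams, phase
panels, each with a manifest that makes the run reproducible) are
available through `tctalpha experiment`; see `tctalpha --help` for the
`simulate`, `sweep-power`, `bifurcation`, `hopf` and `phase` verbs.

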