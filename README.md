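# thalatrack

Real-time estimation of the *hidden* dynamics of a thalamocortical (TC) relay
neuron from nothing but its noisy membrane potential.

In Parkinson's disease, sustained inhibition from the globus pallidus internus
(GPi) de-inactivates the relay cell's low-threshold T-type calcium current,
turning faithful spike relay into pathological rebound bursting.  The variables
that carry this mechanism — the sodium inactivation gate *h* and the T-current
de-inactivation gate *ω* — cannot be measured in an experiment.  `thalatrack`
reconstructs them, together with the unknown synaptic current, by running an
unscented Kalman filter (UKF) around a reduced conductance-based neuron model.

The package contains, as importable library code:

- **`thalatrack.model`** — the reduced three-variable TC relay cell
  (Rubin–Terman 2004 kinetics):

  ```
  C_m dV/dt = −I_L − I_Na − I_K − I_T + I_Gi→Th + I_SM
  dh/dt     = a_h(V)(1−h) − b_h(V)h
  dω/dt     = (ω_∞(V) − ω)/τ_ω(V)
  ```

  with I_L = g_L(V−E_L), I_Na = g_Na m_∞³(V) h (V−E_Na),
  I_K = g_K [0.75(1−h)]⁴ (V−E_K), I_T = g_T p_∞²(V) ω (V−E_T); square-wave and
  gamma-distributed pulse-train sensorimotor inputs; normal vs Parkinsonian
  GPi regimes; forward-Euler integration.
- **`thalatrack.linearize`** — the cost-efficient TC (CETC) variant: every
  nonlinear gating map replaced by continuous piecewise-linear segments whose
  slopes are sums of at most three signed powers of two (evaluable in hardware
  with barrel shifts and adders), plus the three approximation-error criteria
  ERR_CF (RMS), NERR_CF% (range-normalized RMS) and MAE over M = 1000 samples.
- **`thalatrack.ukf`** — the joint state-and-parameter filter on the augmented
  state x = [I_ext, V, h, ω] with the 2N symmetric sigma-point set
  x̄ ± columns of √(N·P), equal weights 1/2N, and observation row
  C = [0 1 0 0].  Exactly reproduces the linear Kalman filter on linear
  systems.
- **`thalatrack.noise`** — Gaussian, 50 / 150 / 350 Hz sinusoidal and mixed
  observation noise.
- **`thalatrack.experiments`** — the evaluation studies: estimation runs
  scored by CF_rmse, batched Q/R sweeps, noise-robustness sweeps, and the
  double-blind protocol (perturbed plant, fully blind filter).
- **`thalatrack.fixedpoint`** — integer emulation of the hardware datapath
  (shift-add function evaluation, integer-sqrt/divide Cholesky).

## Worked example

```sh
python examples/03_estimate_hidden_states.py
```

simulates 2 s of square-wave-driven relay activity, adds 1 mV Gaussian noise
to the voltage, and filters with Q = 5·10⁻⁵, R = 5:

```
post-burn-in CF_rmse per state component:
   i_ext: 0.2670
       v: 0.3048
       h: 0.0055
       w: 0.0132
```

The voltage is tracked well below the noise floor, and the two hidden gates —
quantities no electrode can reach — are recovered to within roughly 1% (h) and
a couple of percent of range (ω) from the voltage alone; `i_ext` is the error
of the recovered pallidal current.  The other examples cover the firing
phenotypes, the shift-add linearization, the Q/R trade-off and the
double-blind run; each prints a short interpretation with its numbers.

A thin CLI mirrors the library (`thalatrack simulate | linearize | estimate |
run | sweep-qr | sweep-noise | double-blind | fixture`).

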