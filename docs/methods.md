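# Methods

## The neuron model

The plant is the reduced thalamocortical relay cell of Rubin & Terman (2004):
fast sodium activation slaved to its steady state m_∞(V), potassium activation
tied to 1−h, leaving three state variables (V, h, ω).  Parameters (densities
per µm², potentials in mV, time in ms): C_m = 1, g_L = 0.05, E_L = −70,
g_Na = 3, E_Na = 50, g_K = 5, E_K = −90, g_T = 5, E_T = 0, with the standard
sigmoid/exponential gating maps (half-voltages −37, −41, −60, −84, −46, −23,
−25 mV).  The channel powers (m_∞³, p_∞², [0.75(1−h)]⁴) and every coefficient
are configurable so that alternative published variants can be substituted
verbatim; a scale factor on τ_ω (default 1.0, i.e. the unmodified source
model) is exposed for the same reason.

The h-equation is integrated in rate form dh/dt = a_h(1−h) − b_h·h.  Its
equilibrium a/(a+b) differs from the tabulated sigmoid h_∞ by under 3% —
h_∞ is used for steady-state current curves and initialization, a/b for the
dynamics, and both are carried (and linearized) separately.

**Inputs.**  The sensorimotor drive is either the relay-fidelity protocol
(square wave: period 25 ms, duty 20%, amplitude 5 pA/µm²) or an irregular
pulse train (monophasic 5 pA/µm² pulses of 5 ms whose inter-pulse intervals
are gamma distributed, mean rate 30 Hz, CV 0.2).  The GPi current is 0 in the
normal regime and a sustained −0.6 pA/µm² in the Parkinsonian regime; the
level was calibrated once so that square-wave relay turns into ≥2-spike burst
events, and a phasic (square-wave) inhibition option exists because
pathological pallidal output is rhythmic in vivo.  All stimulus amplitudes
are treated as current densities; with C_m = 1 pF/µm² a value quoted in mV
per step is numerically identical.

**Numerics.**  Forward Euler at Δt = 0.01 ms (stable well past the spike
upstroke; halving Δt changes the voltage trace proportionally, the expected
first-order behaviour, verified in the tests).  Gates are clamped to [0, 1]
after each step.  The resting state is found by root-finding on the
steady-state current (most hyperpolarized stable zero, scipy brentq), with a
5 s relaxation fallback for parameter sets without a bracketed root.  Spikes
are upward crossings of −20 mV merged within 2 ms.

## The CETC (shift-add piecewise-linear) reduction

Each of the eight nonlinear maps f₁ = m_∞³, f₂ = p_∞², f₃ = [0.75(1−h)]⁴,
f₄ = h_∞, f₅ = a_h, f₆ = b_h, f₇ = ω_∞, f₈ = 1/τ_ω is replaced by a
continuous piecewise-linear function with uniform breakpoints whose slopes
are sums of at most 3 signed powers of two with exponents in [−10, 4] — the
set evaluable in multiplierless hardware with barrel shifters and adders.
Fitting: an unconstrained least-squares continuous fit supplies ideal slopes;
each slope is quantized to the nearest representable value and refined by a
greedy per-segment search over neighbouring representable values, with the
single free offset re-optimized in closed form after every change (intercepts
follow from slopes plus continuity).  Voltage-dependent functions are fitted
on [−120, 20] mV; f₃ on its natural gate domain [0, 1].

Error criteria over M = 1000 uniform samples: ERR_CF is the root-mean-square
deviation, NERR_CF% normalizes it by the range of the linearized function (in
percent), MAE is the mean absolute deviation.  Both definitions live in one
function each so an alternative printed form can replace them.  Note that
MAE ≤ ERR_CF pointwise under these definitions, so a report with mean
MAE > mean ERR_CF cannot arise here.

The default is 16 segments per function (mean NERR_CF% ≈ 0.7).  Eight
segments already satisfy the 2% mean error target but leave the sodium
activation too coarse near threshold to sustain spiking — accuracy of the
printed criteria does not guarantee preserved dynamics, so the default was
chosen by requiring spike-count agreement with the original model under the
relay protocol (exact in the normal state; in the bursty Parkinsonian state
intra-burst spike alignment drifts and per-variable RMS deviations are
correspondingly larger, which the tests bound loosely rather than assert
equal).

## The filter

Augmented state x = [I_ext, V, h, ω]: one random-walk parameter plus the
neuron state, observation row C = [0 1 0 0].  Sigma points are the symmetric
2N set x̄ ± columns of √(N·P) with equal weights 1/(2N) — eight points for
N = 4, no central point, which reproduces mean and covariance exactly and
makes the filter *exact* on linear dynamics (asserted to 1e−6 against a
textbook Kalman filter).  The Cholesky factorization retries with escalating
diagonal jitter (1e−10 ×10 up to 1e−4) before declaring divergence.  Because
the observation model is linear, the measurement update uses the a-priori
covariance directly (K = P⁻Cᵀ/(CP⁻Cᵀ + R)); deriving the observation
covariance from the propagated sigma scatter instead would omit the process
noise from the gain and break the linear-filter equivalence.

Sigma-point gates are *not* clamped to [0, 1] during propagation (a config
flag restores clamping).  The gating ODEs are contraction maps slightly
outside the unit interval, so unclamped points remain stable, whereas
clamping before the moment computation asymmetrically truncates the ensemble
whenever the posterior sits near a boundary — at rest h ≈ 0.997, and clamping
was measured to bias it downward by ~0.07 and ω upward by ~0.04, an order of
magnitude above the filter's actual error.

**Process noise.**  A scalar Q expands to Q·I₄; diagonal or full matrices are
accepted.  The standard estimation runs use the operating point Q = 5·10⁻⁵,
R = 5.  In the double-blind runs the quoted Q (5·10⁻³ normal, 0.5
Parkinsonian) is interpreted as the random-walk intensity of the *estimated
current* with the dynamic components fixed at diag(5·10⁻⁵, 10⁻⁸, 10⁻⁸): a
gate random walk with per-step variance 0.5 is meaningless for a [0, 1]
variable and destabilizes the filter, whereas tiny gate noise encodes that
the gate equations are exact model knowledge and removes the degeneracy
between the estimated current and the calcium gate (both act additively on
dV/dt at subthreshold voltages).

**Known vs blind input.**  In the standard runs the experimenter-applied
sensorimotor stimulus is passed to the filter as a known control input — as
in a dynamic-clamp experiment, where the injected waveform is known — and
I_ext estimates the unknown pallidal current.  With the pulsed stimulus fully
unknown at Q = 5·10⁻⁵ the pair (I_ext, ω) is not identifiable between spikes
(the current estimate settles near a constant and ω absorbs the misfit), so
fully blind operation is reserved for the sweeps and the double-blind
protocol, which are about robustness rather than operating-point accuracy.

**Sampling.**  The plant is integrated at 0.01 ms; observations are taken at
0.05 ms (20 kHz, a routine acquisition rate) and the filter's internal Euler
step equals the observation interval.  The filter's internal model defaults
to the CETC variant; a flag selects the original closed forms.  Estimation
error is CF_rmse, the post-burn-in (100 ms) root-mean-square deviation per
state component.  An ensemble of independent filters (different noise
realizations, per-filter Q/R) runs batched through one vectorized pass.

## Study conditions

* **Recovery run**: normal state, square-wave relay, 1 mV Gaussian noise,
  Q = 5·10⁻⁵, R = 5, 2 s, 20 noise realizations; medians of CF_rmse(h) and
  CF_rmse(ω) are the headline numbers.
* **Q/R sweeps**: blind, 2 s, 20 realizations per cell.  Both error curves
  are genuinely U-shaped: trusting noisy measurements (small R, large Q)
  costs through noise feed-through, trusting the model (large R, small Q)
  costs through sluggish tracking of the unknown current and slow settling.
  The default grids — R ∈ {0.5, 5, 50, 500, 5000} at fixed Q = 5·10⁻⁶ and
  Q ∈ {5·10⁻⁸ … 5·10⁻⁴} at fixed R = 5 — sit on the branches where the
  documented trends (V and h error rank-increasing in R, rank-decreasing in
  Q, ω insensitive to R within a factor 3) are expressed; monotonicity is
  asserted as the sign of the Spearman rank correlation of the cell medians.
  A grid spanning both branches of the U cannot be monotone for any filter.
* **Noise robustness**: blind, strengths {1, 2, 4} mV (amplitude for
  sinusoids, SD for Gaussian; sinusoid phases drawn per realization), both
  regimes, Q = 5·10⁻⁵, R = 5.  The 50 Hz component dominates because it is
  slow relative to the membrane time constant: the filter cannot separate it
  from genuine voltage drift, while 150/350 Hz and white noise average out.
  The mixture inherits the 50 Hz error and exceeds every component.
* **Double-blind**: plant conductances and half-voltages scaled by
  independent U(0.9, 1.1) factors, gamma pulse-train input, filter fully
  blind with the stated (R, Q) pairs.  The slow-gate yardstick is the
  no-filter readout ω_∞(V_obs): in the Parkinsonian state ω strays far from
  quasi-steady state during rebound bursts and the filter beats the readout
  severalfold.  The single-draw ratio varies strongly with the perturbation
  draw (the readout's error is dominated by how far the drawn ω_∞
  half-voltage sits from the filter's), so the headline statistic is the
  median over seven seeded draws per regime.
  The recovered current is additionally required to settle on the pallidal
  level during input-free stretches (samples within 20 ms of a pulse are
  excluded so the cell's own response decay does not contaminate the
  plateau).

## What the synthetic data does and does not show

All data are generated by the package's own plant: a single-compartment
deterministic neuron, perfectly uniform sampling, stationary additive noise,
and (outside the double-blind protocol) a filter model drawn from the same
family.  Real recordings add electrode kinetics, non-stationary artifacts,
channel noise, morphology and currents absent from the model (e.g. the
sag/adaptation currents whose absence the double-blind current estimate
exposes as baseline fluctuation).  Passing tests therefore demonstrate the
estimator's correctness and its robustness to parameter mismatch and
measurement noise — not performance on biological tissue.

## Fixed-point emulation

The datapath model uses 32-bit words with 16 fraction bits (the accumulator
width; the FPGA's 18-bit DSP granularity constrains multipliers, not
accumulation).  Piecewise-linear functions evaluate with barrel shifts and
adds only; the Cholesky recurrence uses the integer square root and integer
division with operands pre-enlarged by a barrel shifter (default prescale
2×16 bits) and rounded back, so reconstruction error falls monotonically with
prescale until it saturates at the format resolution.  A non-positive pivot
after quantization raises an error, mirroring the hardware failure mode.

## Known limitations

* The gating closed forms follow the published source model; if the original
  coefficient tables for the piecewise segments become available they can be
  loaded verbatim through the CSV coefficient interface, but segment counts
  and breakpoints here are the package's own.
* The double-blind margin over the quasi-steady readout is a draw-median
  statistic; individual perturbation draws can fall below it, especially in
  the normal state where true ω rarely leaves quasi-steadiness.
* Euler-only integration (a deliberate mirror of the hardware); no
  square-root/UD filter variants, no smoothing, no adaptive Q/R.
* Parkinsonian-state CETC trajectories dephase within bursts; only coarse
  RMS bounds and burst/spike statistics are comparable there.
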