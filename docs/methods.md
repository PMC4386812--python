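# Methods

## Scope

This package implements four reductions of a barn-owl nucleus laminaris (NL)
coincidence-detector neuron — a two-compartment active integrate-and-fire
(IF) model, a single-compartment active IF model, a single-compartment
passive IF model, and a non-spiking subthreshold variant — plus the
stochastic binaural input model and the evaluation protocols used to compare
them with in vivo physiology. The full Hodgkin–Huxley parent model (nodal
Na/K_HVA conductances) is out of scope, as are implicit/exponential
integrators and wall-clock benchmarking.

## Membrane model

Unit system: mV, ms, nS, pF, pA (so nS·mV = pA, pA/pF = mV/ms; 1/nS = GΩ).
The soma obeys

    C_soma dV/dt = g_L(E_L − V) + ḡ_KLVA d(V,t)(E_K − V)
                   + g_syn(t)(E_syn − V) + I_IF + I_ext

with C_soma = 24 pF, g_L = 48 nS (240 nS passive), ḡ_KLVA = 192 nS (0
passive), E_L = −60 mV, E_K = −75 mV, E_syn = 0 mV. In the two-compartment
variant a nodal compartment (C = 0.2 pF, g_L = 2 nS) couples to the soma via
g_axon = 117.8 nS and carries the IF unit; in the single-compartment
variants the IF unit acts on the soma directly. The K_LVA gate follows
first-order relaxation dd/dt = (d_∞ − d)/τ_d with the slice-derived rates
α_d(V) = 0.20·e^{(V+60)/21.8}, β_d(V) = 0.17·e^{−(V+60)/14} (1/ms),
d_∞ = α/(α+β), τ_d = Q10^{−(T1−T0)/10}/(α+β).

Two typeset ambiguities in the source equations were resolved on physical
grounds and are exposed in configuration:

- **Relaxation sign.** The literal reading dd/dt = (d − d_∞)/τ_d is
  unstable; the standard relaxation toward d_∞ is the only reading
  consistent with bounded activation and phasic firing.
- **Q10 exponent.** A literal reading multiplies τ_d by Q10^{(T1−T0)/10},
  i.e. *slows* kinetics on warming from 23 °C to 40 °C. We apply the
  physiological speed-up convention (÷ 2.5^1.7 ≈ 4.74); `KLVAKinetics(speedup=False)`
  forces the literal reading.

The thresholding unit injects I_IF = I_const + I_spike with I_const = 200 pA
and I_spike(t) = A1 e^{−t/τ1} + A2 e^{−t/τ2} (τ1 = 0.02, τ2 = 0.20 ms;
A1/A2/V_θ per variant: 4000/3000/−56.7 two-compartment, 3500/3000/−58.3
one-compartment active, 4000/4000/−58.6 passive). Detection is *level*
semantics: outside the absolute refractory period (T_ref = 0.9 ms,
detection-only — membrane dynamics and decaying spike currents continue), a
monitored potential at or above V_θ fires at the end of the Euler step on
which the condition holds; successive spike currents superpose linearly.

## Numerics

Integration is explicit (forward) Euler on a fixed grid. Two terms are
treated with exact discrete-time updates, which is why exponentials were
chosen for the spike current in the first place:

- the spike-current state (s1, s2) decays by exp(−dt/τᵢ) per step and is
  incremented by (A1, A2) at each crossing, so it equals the superposed
  closed form at every grid point to machine precision at any dt (pinned at
  1e−9 relative tolerance in the tests);
- its contribution to dV/dt uses the exact per-step charge, an effective
  current sᵢ·τᵢ(1 − e^{−dt/τᵢ})/dt. A left-sampled Euler term instead
  over-delivers the τ1 = 20 µs component's charge by ~27 % at dt = 10 µs,
  visibly inflating spike amplitude and rate as dt grows.

The synaptic conductance is evaluated exactly at grid points from the exact
(off-grid) presynaptic event times — each event contributes
α(t − t_event) truncated at 10 τ_α (residual < 3×10⁻⁴ of peak) — and is held
piecewise-constant over each step. Membrane terms are first order; halving
dt at fixed input shrinks the subthreshold error ≥ 1.8× (tested). Initial
state: V at the variant's resting potential (root of the steady-state
current balance), d = d_∞(V₀), node at its conditional steady state,
s1 = s2 = 0. Non-finite states abort with an error: the nodal compartment's
time constant is 1.67 µs, so the two-compartment variant is Euler-unstable
for dt > 3.3 µs by design of the original circuit, not by implementation
choice. A transparent single-step reference (`euler_step`) and the compiled
production loop are held equal by a dedicated test.

## Synaptic input model

Each of M = 150 fibers per side is an inhomogeneous Poisson process with von
Mises intensity λ(t) = λ₀ e^{κ cos 2πf t}/I₀(κ), λ₀ = 500 Hz, f = 4 kHz,
with κ solved from the fiber vector strength r = I₁(κ)/I₀(κ) = 0.6
(κ ≈ 1.516). The source defers the exact intensity form to prior work we
could not consult; the von Mises family is the canonical circular-statistics
choice with the correct mean-rate/vector-strength parametrization, and the
generator is pluggable. Realizations use thinning against the peak intensity,
with one master seed and per-fiber `SeedSequence` substreams so a fiber's
train is independent of generation order. All fibers on a side share locking
phase zero; the interaural phase difference δ shifts the contralateral
conductance circularly by round(δ/2πf/dt) grid steps, so one realization
serves a whole δ grid (common random numbers). Events drive the alpha
conductance α(t) = H_α (t/τ_α) e^{1−t/τ_α} with H_α = 1.3 nS and half-width
W_α = 2.446 τ_α = 0.1 ms; the summed 300-fiber drive has mean
rate·H_α·e·τ_α ≈ 21.7 nS.

What the generator does *not* emulate: synaptic depression/facilitation,
conduction-delay jitter, frequency-dependent vector strength, and any
across-fiber correlation beyond the shared locking phase. Protocol results
therefore characterize the models under idealized stationary drive, not the
full variability of the in vivo afferent population.

## Protocols

- **Step-current classification.** The model is held at −60 mV by a
  computed holding current, settled 20 ms, then stepped for 50 ms.
  *no_spike* = no spike during the step; *phasic* = all spikes within the
  first 5 ms (the onset window, configurable — the source defines the
  classes only verbally); *tonic* otherwise.
- **Average spike shape.** 300 homogeneous-Poisson fibers at 500 Hz;
  output spikes aligned at the threshold-crossing sample and averaged over
  [−1, +2] ms (1500 spikes, dt = 2 µs by default so the 20-µs spike-current
  component is resolved). Amplitude = peak − baseline with the baseline the
  waveform mean over [−1.0, −0.5] ms; the peak-minus-V_θ convention is
  reported alongside since the source does not define its baseline.
- **Rate–phase curves.** Spike rate per δ (default −2π…2π, π/8 spacing;
  10 s per point at dt = 10 µs, first 20 ms discarded), in-phase/out-of-phase
  rates read at the grid points nearest δ = 0 and ±π. Rates carry Poisson
  standard errors √N/T; stochastic test comparisons use 2 SE.
- **Threshold / refractory sweeps.** Rates at δ = 0 and π across a V_θ grid
  (default ±2.5 mV around the variant default, 0.2-mV steps) or a T_ref grid,
  reusing one input realization across the grid. The width of the interval
  where modulation depth (in − out) exceeds 180 spikes/s is measured with
  linear interpolation between grid points.
- **Time-step reliability.** For candidate steps (defaults 1–30 µs
  one-compartment, 0.5–5 µs two-compartment) the same presynaptic event
  times are re-sampled per grid and integrated live; each candidate is
  compared at its own grid points with a 0.1-µs reference that *replays* the
  candidate's spike times as forced injections. A raw trajectory comparison
  is uninformative here: with stochastic 4-kHz drive, oscillation peaks graze
  within ~0.1 mV of threshold several times per second, so single spikes flip
  between any two grids and the maximum discrepancy saturates at a full spike
  height even at dt = 1 µs. The replay comparison isolates integration error,
  is deterministic and monotone in dt, and localizes unreliability at spike
  initiation. A step is unreliable if any of three 1-s traces deviates
  > 0.5 mV; integration blow-up counts as unreliable.

## Known limitations

- **Passive-variant operating point.** Under the stated drive the passive
  variant's mean potential is ≈ −54.3 mV — the synaptic DC that the active
  variants cancel through K_LVA (driven mean ≈ −60.2 mV) depolarizes it by
  ~6 mV — which is *above* its default threshold −58.6 mV. Its binaural
  rates therefore saturate near 1/T_ref (≈ 1110 spikes/s; in-phase rate far
  above the typical discharge range, as expected for this variant), its
  refractory sensitivity reflects pure refractory limiting (≈ 620 spikes/s
  change from T_ref 0.8 → 1.6 ms), and its threshold-sweep transition sits
  near −53 mV rather than near the default threshold. The *width* of its
  modulation-depth interval (≈ 1.8 mV) is measured around that actual
  transition. Quantitative passive-variant benchmarks tied to the default
  threshold should be read with this operating-point caveat in mind.
- **Reliability envelope.** The measured maximum allowable step for the
  single-compartment models is 5–10 µs (the discrepancy at 10 µs sits within
  a few hundredths of a millivolt of the 0.5-mV criterion, so the reported
  value can fall on either side across seeds; 15 µs exceeds the criterion by
  ~1.5× under every Euler variant we tested — left/midpoint/bin-averaged
  input sampling crossed with plain/exact-charge spike currents). About 70 %
  of the 10–15-µs error is subthreshold input-sampling error (holding g
  constant per step lags the 4-kHz drive by dt/2), the rest spike-transient
  shape error. The two-compartment variant is reliable at 2 µs and
  unreliable from 3 µs (nodal oscillation threshold 2 τ_node ≈ 3.3 µs).
- Rates and sweep statistics at the default 10-s-per-point durations carry
  ~5–7 spikes/s standard errors; the tests budget 2 SE accordingly.
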