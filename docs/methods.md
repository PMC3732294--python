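# Methods

## Model overview

`spikeseg` simulates a two-layer network of conductance-based leaky
integrate-and-fire (gLIF) neurons.  The input layer (default 512 excitatory
cells on a ring, 128 interneurons) represents a one-dimensional "retina";
the output layer (256 excitatory cells on a 16×16 grid, 64 interneurons)
learns object representations through plastic feed-forward synapses.  All
other projections are fixed:

| projection | structure | class constants |
|---|---|---|
| input E → output E | full, plastic, w ∈ [0, 1] init U(0, 1) | E_rev 0 mV, τ 2 ms, ΔG 3.75 nS |
| input E → input E | Gaussian ring profile, symmetric, no self-synapses | E_rev 0 mV, τ 2 ms, ΔG 5 nS |
| E → I (within layer) | uniform, full | E_rev 0 mV, τ 2 ms, ΔG 5 nS |
| I → E (within layer) | uniform, full | E_rev −70 mV, τ 5 ms, ΔG 5 nS |

The output layer has no lateral excitation.  Inhibitory pools are private to
their layer.  An optional uniform I → I projection exists but is off by
default (weight 0).

### Membrane equation

With potentials in mV, conductances in nS, capacitance in pF, currents in
nA and time in ms (so that pA/pF integrates to mV/ms without conversion
factors):

    C dV/dt = g_leak(E_rest − V) + Σ_c g_c(E_c − V) + g_AHP(E_K − V)
              + I_ext + σ_noise dW/dt

Cellular constants (excitatory / inhibitory): C = 500/214 pF, g_leak =
25/18 nS (τ_m = 20/12 ms), E_rest = −74/−82 mV, threshold −53 mV, absolute
refractory period 2 ms.  The inhibitory after-spike potential is −58 mV.
The excitatory after-spike value is specified only as a 4 mV
hyperpolarization; we interpret it **relative to threshold**, V_reset =
−53 − 4 = −57 mV (an absolute reading of +4 mV is unphysical).  It is
configurable.

Adaptation: every spike of a principal cell raises a potassium conductance
by ΔG_AHP = 6 nS; it decays with τ_Ca = 50 ms and drives the membrane
toward E_K = −80 mV.  We track the calcium concentration directly in
conductance units (the binding constant is folded into the increment), so
`NetworkState.ca` is the adaptation conductance in nS.  Interneurons carry
no adaptation; for them E_K is inert, which is why the E_K ≤ E_rest sanity
check applies only to adapting cells (the inhibitory resting potential of
−82 mV lies below E_K).

Membrane noise is an additive Wiener increment of standard deviation
σ_noise·√dt per step with σ_noise = noise_frac × (V_thresh − V_reset).  The
noise fraction is a free constant of the model; the default 0.02 is enough
to break the symmetry between identically driven stimulus pools without
causing spontaneous firing (a zero-cue network stays silent).

### Numerical scheme

Forward Euler at dt = 0.02 ms (full scale) or 0.05 ms (scaled experiments).
Update order per step, fixed for reproducibility:

1. decay synaptic conductances and the adaptation conductance,
2. deliver the previous step's spikes to postsynaptic conductances
   (one-step synaptic latency; no axonal delays),
3. Euler membrane update with noise,
4. threshold test (V ≥ V_thresh after the step, no crossing interpolation),
5. reset: V → V_reset, refractory clock armed, adaptation increment;
   then the plasticity update for this step's spikes (traces first, then
   LTP, then LTD).

The linear decay sub-equations (synaptic conductances, adaptation, STDP
traces) use the exact per-step factor exp(−dt/τ) rather than the Euler
factor (1 − dt/τ): it is unconditionally stable, keeps all conductances
non-negative, and at these step sizes is indistinguishable from the Euler
factor (relative difference < 2·10⁻⁴ over one τ).  The membrane equation
itself, whose coupling is nonlinear, is integrated by plain Euler; a
single-neuron check against a 20× finer reference integration keeps every
spike within 0.1 ms over 500 ms.

Because all synapses of one class share one τ, per-synapse conductances sum
linearly and are stored as one per-(neuron, class) trace — mathematically
identical and O(N) instead of O(N²).

### Lateral connectivity

Distances on the ring/torus use per-dimension wraparound
min(|Δ|, L − |Δ|).  The lateral excitatory weight is a Gaussian of the
distance, w(d) = w_max·exp(−d²/2σ_lat²), cut off at a radius of half the
layer (configurable), with σ_lat defaulting to half the stimulus width —
the spread found optimal when sweeping (the package reproduces that sweep).
The peak weight w_max = 1 puts the peak lateral conductance at the fixed
class scaling of 5 nS.  Connection probabilities default to 1 (values are
not published); they are configurable and the probabilistic masks are drawn
symmetrically.

The interneuron loop carries the long-range inhibitory arm of the Mexican
hat.  The published tables mask its uniform weights; they were tuned once,
by inspecting the input-layer dynamics only (clean single-volley
oscillations, no runaway firing), and then frozen: w(E→I) = 0.2,
w(I→E) = 1.0 in units of the 5 nS class scaling.  With weaker inhibition
the pools fire multi-spike bursts, over-accumulate adaptation and stall in
long silences; with stronger E→I drive volleys truncate to single spikes.

### STDP

Per-neuron traces (exact because they depend on one spike train only):

    pre spike:  C ← C + a_pre(1 − C),  dC/dt = −C/τ_pre,  τ_pre = 15 ms
    post spike: D ← D + a_post(1 − D), dD/dt = −D/τ_post, τ_post = 25 ms

with a_pre = a_post = 0.5 (the two 0.5 constants of the synaptic parameter
set are identified with the trace increments).  Weight updates couple each
spike train with the opposite trace, multiplicatively soft-bounded:

    post spike of j:  w_ji ← w_ji + η C_i (w_max − w_ji)
    pre spike of i:   w_ji ← w_ji − η D_j w_ji

η = 0.1, w ∈ [0, 1].  A mixed variant with additive LTP is available
(`mode="additive_ltp"`); the fully multiplicative form is the default.
Plasticity runs only during training; testing phases freeze the weights.

## Stimuli and protocol

Stimuli are contiguous blocks of input neurons receiving a tonic cue
current (0.75 nA default).  A stimulus of width w presented at T transforms
with shift s < w yields (w − s)/w overlap between consecutive positions —
75 % at the default w = 64, s = 16, T = 13 — which is what lets
continuous-transformation learning associate them.  The protocol is
pretest → train × epochs → posttest:

* **testing**: every transform of every stimulus alone for one cue period,
  plasticity off, full dynamic-state reset between presentations;
* **training**: all stimuli on simultaneously, translating in lock-step;
  one sweep direction (ascending/descending) drawn per epoch, all
  transforms visited in order (a per-step random-walk policy is available);
  dynamic state persists within the training phase and is reset at phase
  boundaries; weights are snapshot after every epoch.

The generator emulates the study conditions exactly (abstract, homogeneous,
equal-strength patches on a 1-D retina, translation as the only
transformation, identical onset for all stimuli).  It does not emulate
natural-image statistics, stimulus-intensity differences, independent
motion, or 2-D geometry, so passing tests demonstrate the segmentation and
invariance-learning mechanism, not performance on realistic scenes.

## Scaled experiment sizes

Simulations in the test suite and the acceptance script run a half-scale
network chosen so a full experiment takes tens of seconds on one CPU:
256 + 64 input cells, 64 + 16 output cells, dt = 0.05 ms.

* **Two stimuli**: width 32, shift 8, 13 transforms (same 75 % overlap),
  σ_lat = 16, cue 0.75 nA for 250 ms per transform, 5 epochs.
* **Four stimuli** (capacity): width 16, shift 4 in quarter pools,
  13 transforms, σ_lat = 8 (half the width), cue reduced to 0.6 nA,
  training extended to 16 epochs.  Three further adjustments compensate
  for halving the per-pool spike counts: the output-layer interneuron
  coupling is strengthened (w(E→I) = w(I→E) = 2.0) so per-volley
  competition still selects sparse winners, the membrane noise fraction is
  raised to 0.05 so transient coalitions between stimulus pools keep
  reshuffling instead of freezing, and testing windows are lengthened to
  500 ms to resolve the sparser output rates (a cell firing once per
  oscillation cycle produces only a handful of spikes per window).

## Analysis conventions

* **Rates**: spikes per (stimulus, transform) cue window / window length.
* **Correlograms**: per-pool population spike counts in 1 ms bins,
  mean-subtracted, Pearson-normalized at circular lags.  Significance:
  95th percentile of the pooled per-lag |correlation| of circularly
  shifted surrogate pairs (200 by default).  A max-over-lags surrogate
  statistic would be degenerate for periodic series, which realign at some
  shift.  `antiphase_metrics` calls two pools "synchronized" when the
  cross-correlation within ±5 ms of zero lag (the di-synaptic latency with
  which one pool's volley can trail another within a cycle) exceeds the
  envelope.
* **Single-cell information**: responses discretized into 10 equal-width
  bins spanning each cell's own response range (constant cells carry
  0 bits); transforms equiprobable within stimulus, stimuli equiprobable;
  reported per (cell, stimulus) with the per-cell maximum over stimuli;
  clipped to [0, log₂S].
* **Decoding**: per cell and stimulus, Gaussian fit to the responses over
  transforms excluding the held-out transform of the true stimulus
  (jackknife); s.d. floor max(observed s.d., 1 % of the cell's range,
  0.1 spikes/s); log-likelihoods summed over the ensemble, softmaxed into
  P(s′|response) and accumulated into the joint table over all S·T trials.
* **Bias correction**: first-order finite-sampling term
  (Σ_s(R_s − 1) − (R − 1)) / (2 N ln 2), with R_s the occupied cells
  (> 10⁻¹²) of conditional row s and R those of the decoded marginal;
  subtracted from the plug-in MI and clipped to [0, log₂S].
* **Multiple-cell curve**: candidate lists are the top `max_cells` cells
  per stimulus by single-cell information; an ensemble of size n is drawn
  stratified (per-stimulus quotas n // S, remainder spread at random,
  members uniform from the stimulus' top list) so each stimulus is
  represented by its own best cells as soon as n allows — pooled uniform
  sampling would often omit a stimulus entirely and bound the decoded
  information below log₂S for purely combinatorial reasons.  Values are
  averaged over an iteration count decreasing linearly from 50 (size 1) to
  10 (size max_cells).
* **Information score**: per stimulus, the count of cells with
  I(s, R) ≥ 0.95·log₂S; the minimum count over stimuli divided by the
  output-layer size.

## Known limitations

* The half-scale four-stimulus experiment falls short of the full-scale
  ceiling: the best output cells reach ≈ 1.7–2.0 bits for three of the
  four stimuli and the decoded multiple-cell plateau reaches ≈ 1.5–1.6 of
  the 2-bit ceiling, with noticeable seed-to-seed variance.  With 64
  output cells and strong competition, one stimulus occasionally ends up
  underrepresented, and output cells firing only 1–2 spikes per volley
  quantize the test-phase rates coarsely.  Both effects shrink with layer
  size; they are properties of the reduced simulation scale, not of the
  mechanism, which the two-stimulus experiment demonstrates at ceiling.
* The sweep over lateral spread reproduces the qualitative shape (interior
  optimum; total failure at zero spread) but at this scale the optimum
  sits at w/4 rather than w/2 and large spreads collapse to zero score
  more abruptly.
* Euler integration with threshold testing after the step makes spike
  times dt-quantized; at 0.02–0.05 ms this is far below every reported
  effect size.
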