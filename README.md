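# spikeseg

A spiking neural network model of how the visual system can learn *separate*,
translation-invariant representations of objects that are **always seen
together, moving together**.

Rate-coded competitive networks fail at this task: when two objects are
always co-active, Hebbian learning binds both onto the same output neurons
(the *superposition catastrophe*). `spikeseg` implements a two-layer network
of conductance-based integrate-and-fire neurons in which

1. **Mexican-hat lateral connectivity** (short-range Gaussian excitation
   between input-layer principal cells, plus uniform coupling to a private
   pool of inhibitory interneurons) synchronises the cells representing one
   object and desynchronises distinct objects, and
2. **spike-frequency adaptation** (a calcium-gated potassium conductance)
   prevents either representation from winning permanently,

so that simultaneously presented stimuli settle into **anti-phase population
oscillations** ("perceptual cycles").  Because the two objects now occupy
different time slots, **spike-timing-dependent plasticity** on the
feed-forward synapses can potentiate each output neuron's afferents from one
object while depressing those from the other — even though both objects are
presented, and translated in lock-step, at every moment of training.
Overlap between consecutive translations then binds all positions of an
object onto the same output cells (continuous-transformation learning),
yielding translation-invariant, stimulus-specific output representations.

## Model

Each neuron obeys a conductance-based leaky integrate-and-fire equation

```
C dV/dt = g_leak (E_rest − V) + Σ_c g_c (E_c − V) + g_AHP (E_K − V) + I_ext + σ dW/dt
```

with per-class exponential synaptic conductances
(`dg_c/dt = −g_c/τ_c` plus `w·ΔG_c` per afferent spike), an adaptation
conductance `g_AHP` that jumps 6 nS at every spike of a principal cell and
decays with τ = 50 ms, threshold −53 mV, after-spike reset and a 2 ms
refractory period.  Feed-forward weights evolve under a trace-based,
multiplicative STDP rule: a presynaptic glutamate trace `C_i` (τ = 15 ms)
drives potentiation `Δw = η C_i (w_max − w)` at postsynaptic spikes, and a
postsynaptic NMDA-unblocking trace `D_j` (τ = 25 ms) drives depression
`Δw = −η D_j w` at presynaptic spikes.

Performance is read out from firing rates with information-theoretic
measures: stimulus-specific single-cell information
`I(s,R) = Σ_r P(r|s) log₂(P(r|s)/P(r))` (ceiling log₂ S), decoded
multiple-cell information (Gaussian Bayesian decoding with jackknife
cross-validation, first-order finite-sampling bias correction, clipped to
the theoretical limits), and an information score counting the output cells
that convey ≥ 95 % of the maximum about the least-well-represented stimulus.

## Worked example

```python
import spikeseg as ss

cfg = ss.scaled_two_stimulus_config(sim_seed=1, init_seed=2)
result = ss.run_experiment(cfg)
for name, info in (("pre", result.info_pre), ("post", result.info_post)):
    best = [round(float(info.single_cell[:, s].max()), 3) for s in range(2)]
    print(name, "best single-cell info per stimulus:", best,
          "| multi-cell:", round(float(info.multi_cell.max()), 3),
          "| score:", round(info.info_score, 3))
```

prints (about 40 s on one CPU):

```
pre best single-cell info per stimulus: [0.048, 0.115] | multi-cell: 0.145 | score: 0.0
post best single-cell info per stimulus: [1.0, 1.0] | multi-cell: 1.0 | score: 0.281
```

Before training no output cell distinguishes the two stimuli (information
near 0 of the 1-bit ceiling).  After five epochs of training — during which
the two stimuli were *never* presented apart — cells for **both** stimuli
reach the 1-bit maximum across all 13 translations, the decoded ensemble
information saturates at 1 bit, and 28 % of the output layer crosses the
95 % information threshold for the worse-represented stimulus.

The same pipeline is available from a shell:

```
spikeseg run --out results/demo          # one experiment + saved artifacts
spikeseg sweep --param sigma_lat --values 0,8,16,32 --seeds 10
spikeseg analyze --results results/demo  # recompute info measures
```

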