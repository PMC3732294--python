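"""Trace-based spike-timing-dependent plasticity on feed-forward synapses.

Each presynaptic (input-layer principal) cell carries a trace ``C`` — a
glutamate-concentration proxy — that jumps towards 1 by a saturating
increment on every presynaptic spike and decays with ``tau_pre``:

    C <- C + a_pre (1 - C)   on a pre spike,   dC/dt = -C / tau_pre.

Each postsynaptic (output-layer principal) cell carries ``D`` — a proxy for
the proportion of NMDA receptors unblocked by back-propagating action
potentials — with increment ``a_post`` and decay ``tau_post``.  Because both
traces depend only on one spike train, they are stored per neuron, which is
exact and O(N) rather than per synapse.

The weight update couples each spike train with the *opposite* trace
(multiplicative, soft-bounded form):

    post spike of cell j:  w_ji <- w_ji + eta C_i (w_max - w_ji)   (LTP)
    pre  spike of cell i:  w_ji <- w_ji - eta D_j w_ji             (LTD)

so pre-before-post potentiates and post-before-pre depresses, with the
asymmetric exponential windows set by ``tau_pre`` / ``tau_post``.  Weights
can never leave ``[w_min, w_max]``.  The mixed variant with an additive LTP
term (``eta C_i`` without the ``w_max - w`` factor, hard-clipped above) is
available as ``mode='additive_ltp'``.

Within a step the traces are updated first, then LTP, then LTD, so
simultaneous pre and post spikes in the same dt apply both (the order
matters only at O(eta^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import STDPParams
from .connectivity import Projection

__all__ = ["TraceState", "update_traces", "apply_stdp", "OnlinePlasticity"]


@dataclass
class TraceState:
    """Per-neuron plasticity traces, both bounded in [0, 1]."""

    c: np.ndarray  # presynaptic trace, one per input principal cell
    d: np.ndarray  # postsynaptic trace, one per output principal cell

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(c=np.zeros(n_pre), d=np.zeros(n_post))

    def reset(self) -> None:
        self.c[:] = 0.0
        self.d[:] = 0.0


def update_traces(traces: TraceState, pre_spikes: np.ndarray,
                  post_spikes: np.ndarray, dt: float,
                  params: STDPParams) -> None:
    """Advance both traces one step: exact exponential decay, then the
    saturating spike increments.  Saturation keeps both traces in [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.c *= math.exp(-dt / params.tau_pre)
    traces.d *= math.exp(-dt / params.tau_post)
    if pre_spikes.any():
        traces.c[pre_spikes] += params.a_pre * (1.0 - traces.c[pre_spikes])
    if post_spikes.any():
        traces.d[post_spikes] += params.a_post * (1.0 - traces.d[post_spikes])


def apply_stdp(w: np.ndarray, traces: TraceState, pre_spikes: np.ndarray,
               post_spikes: np.ndarray, params: STDPParams) -> None:
    """Apply the weight updates for one step's spikes, in place.

    LTP first (rows of spiking postsynaptic cells), then LTD (columns of
    spiking presynaptic cells).
    """
    if post_spikes.any():
        rows = w[post_spikes]
        if params.mode == "multiplicative":
            rows += params.eta * traces.c[None, :] * (params.w_max - rows)
        else:  # additive LTP, hard-bounded above
            rows += params.eta * traces.c[None, :] * (params.w_max - params.w_min)
            np.minimum(rows, params.w_max, out=rows)
        w[post_spikes] = rows
    if pre_spikes.any():
        cols = w[:, pre_spikes]
        cols -= params.eta * traces.d[:, None] * cols
        w[:, pre_spikes] = cols
    np.clip(w, params.w_min, params.w_max, out=w)


class OnlinePlasticity:
    """Online STDP hook bound to one plastic projection.

    ``step`` is called once per integration step by the simulator with the
    boolean pre/post spike vectors of the projection; it advances the traces
    and applies the weight rule in place on ``projection.w``.
    """

    def __init__(self, projection: Projection, params: STDPParams):
        if not projection.plastic:
            raise ValueError("OnlinePlasticity requires a plastic projection")
        self.projection = projection
        self.params = params
        self.traces = TraceState.zeros(len(projection.pre), len(projection.post))

    def step(self, pre_spikes: np.ndarray, post_spikes: np.ndarray,
             dt: float) -> None:
        update_traces(self.traces, pre_spikes, post_spikes, dt, self.params)
        if pre_spikes.any() or post_spikes.any():
            apply_stdp(self.projection.w, self.traces, pre_spikes,
                       post_spikes, self.params)

    def reset(self) -> None:
        self.traces.reset()
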