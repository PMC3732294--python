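"""Conductance-based leaky integrate-and-fire dynamics.

The membrane potential of every cell follows

    C_m dV/dt = g_leak (E_rest - V) + I_syn + I_AHP + I_ext + noise,

integrated by forward Euler at a fixed step.  ``I_syn`` sums the per-class
synaptic conductances times their driving forces (Eq. form
``sum_c g_c (E_c - V)``); ``I_AHP = g_AHP (E_K - V)`` is the
after-hyperpolarization (adaptation) current whose conductance grows by a
fixed amount with every spike of a principal cell and decays with the
calcium time constant.  Spiking is detected by threshold crossing after the
Euler step; the membrane is then clamped at the hyperpolarization potential
for the absolute refractory period.

Linear decay sub-equations (synaptic conductances, adaptation conductance,
plasticity traces) are advanced with their exact per-step decay factor
``exp(-dt/tau)``; only the membrane equation, whose coupling is nonlinear,
uses the plain Euler increment.  At dt = 0.02-0.05 ms the two choices agree
to well below the integration error, and the exact factor can never produce
a negative conductance.

Update order within one step (fixed for reproducibility):

1. decay conductances and the adaptation conductance,
2. deliver the spikes emitted on the *previous* step to postsynaptic
   conductances (one-step synaptic latency, no axonal delays),
3. advance the membrane with noise,
4. threshold test,
5. reset (spiking cells: V to the hyperpolarization potential, refractory
   clock armed, principal cells get the adaptation increment), then the
   plasticity update for the step's spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .connectivity import CellArrays, Network
from .config import SynapseClassParams

__all__ = [
    "NetworkState",
    "resting_state",
    "synaptic_current",
    "conductance_step",
    "adaptation_step",
    "membrane_step",
    "apply_reset",
    "simulate_window",
]


@dataclass
class NetworkState:
    """Dynamic variables of the whole network at one instant.

    ``v``: membrane potentials (mV); ``g``: summed synaptic conductances
    (nS), one column per afferent synapse class; ``ca``: adaptation
    (potassium) conductance tracking the calcium concentration, in nS so
    that each spike increments it by the per-spike conductance step;
    ``ref_remaining``: remaining refractory time (ms); ``t``: time (ms).
    """

    v: np.ndarray
    g: np.ndarray
    ca: np.ndarray
    ref_remaining: np.ndarray
    t: float = 0.0

    def reset(self, cells: CellArrays) -> None:
        """Return all dynamic variables to rest (weights are not touched)."""
        self.v[:] = cells.e_rest
        self.g[:] = 0.0
        self.ca[:] = 0.0
        self.ref_remaining[:] = 0.0
        self.t = 0.0


def resting_state(network: Network) -> NetworkState:
    n = network.n
    return NetworkState(
        v=network.cells.e_rest.copy(),
        g=np.zeros((n, network.n_classes)),
        ca=np.zeros(n),
        ref_remaining=np.zeros(n),
    )


def synaptic_current(state: NetworkState,
                     classes: list[SynapseClassParams]) -> np.ndarray:
    """Total synaptic current per neuron in pA (positive = depolarizing).

    ``sum_c g_c (E_rev_c - V)`` with g in nS and V in mV gives pA directly.
    """
    e_rev = np.array([c.e_rev for c in classes])
    return ((e_rev[None, :] - state.v[:, None]) * state.g).sum(axis=1)


def conductance_step(state: NetworkState, classes: list[SynapseClassParams],
                     dt: float, incoming=None, _decay=None) -> None:
    """Decay every class conductance and add arriving spike increments.

    ``incoming`` is an iterable of ``(class_index, post_indices,
    increments_nS)`` triples; increments are the presynaptic weights summed
    per postsynaptic cell and already scaled by the class ``dg``.  The exact
    exponential decay factor keeps conductances non-negative for any dt, so
    the clamp against negative values required by an explicit-Euler decay is
    unnecessary here.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if _decay is None:
        _decay = np.exp(-dt / np.array([c.tau_syn for c in classes]))
    state.g *= _decay[None, :]
    if incoming:
        for cls_idx, post, amounts in incoming:
            if np.any(np.asarray(amounts) < 0):
                raise ValueError("conductance increments must be non-negative")
            state.g[post, cls_idx] += amounts


def adaptation_step(state: NetworkState, cells: CellArrays, dt: float,
                    spikes: np.ndarray | None = None,
                    _decay=None) -> None:
    """Decay the adaptation conductance; credit spikes if supplied.

    ``simulate_window`` calls this with ``spikes=None`` at the top of each
    step because :func:`apply_reset` credits the per-spike increment at the
    moment of the spike (stage 5); passing a spike vector here supports
    standalone use of the operator.
    """
    if _decay is None:
        _decay = np.exp(-dt / cells.tau_ca)
    state.ca *= _decay
    if spikes is not None and spikes.any():
        state.ca += spikes * cells.dg_ahp


def membrane_step(state: NetworkState, cells: CellArrays,
                  classes: list[SynapseClassParams], i_ext: np.ndarray,
                  dt: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """One forward-Euler membrane update; returns the boolean spike vector.

    ``i_ext`` is the externally injected current in nA per neuron.  The
    noise term is an additive Gaussian increment of standard deviation
    ``sigma_noise * sqrt(dt)`` (Wiener increment scaled per cell).
    Refractory neurons are held at their reset potential and their clock is
    decremented.  Non-finite potentials abort the simulation: they signal an
    unstable dt/parameter combination.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    not_ref = state.ref_remaining <= 0.0
    i_total = cells.g_leak * (cells.e_rest - state.v)
    i_total += synaptic_current(state, classes)
    i_total += state.ca * (cells.e_k - state.v)
    i_total += i_ext * 1000.0  # nA -> pA
    dv = (dt / cells.c_m) * i_total
    if rng is not None and np.any(cells.sigma_noise > 0):
        dv = dv + cells.sigma_noise * math.sqrt(dt) * rng.standard_normal(cells.n)
    state.v = np.where(not_ref, state.v + dv, cells.v_reset)
    state.ref_remaining = np.maximum(state.ref_remaining - dt, 0.0)
    if not np.all(np.isfinite(state.v)):
        bad = int(np.flatnonzero(~np.isfinite(state.v))[0])
        raise FloatingPointError(
            f"non-finite membrane potential at neuron {bad}, t={state.t:.3f} ms; "
            "integration is unstable for the chosen dt/parameters"
        )
    return not_ref & (state.v >= cells.v_thresh)


def apply_reset(state: NetworkState, cells: CellArrays,
                spikes: np.ndarray) -> None:
    """After-spike resetting: clamp V, arm the refractory clock, and add the
    adaptation increment (principal cells only; interneurons carry none)."""
    if not spikes.any():
        return
    state.v[spikes] = cells.v_reset[spikes]
    state.ref_remaining[spikes] = cells.t_ref[spikes]
    state.ca += spikes * cells.dg_ahp


def _contiguous_slice(idx: np.ndarray) -> slice | np.ndarray:
    if idx.size and np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
        return slice(int(idx[0]), int(idx[-1]) + 1)
    return idx


def simulate_window(network: Network, i_ext: np.ndarray, duration: float,
                    dt: float, rng: np.random.Generator | None = None,
                    state: NetworkState | None = None, plasticity=None,
                    t_offset: float = 0.0):
    """Integrate the full network for ``duration`` ms.

    ``i_ext`` is the constant per-neuron injected current (nA) over the
    window.  ``plasticity`` is an optional online STDP hook (see
    :class:`spikeseg.plasticity.OnlinePlasticity`) advanced once per step
    with the feed-forward pre/post spike vectors.  Returns
    ``(neuron_ids, spike_times_ms, state)`` with times offset by
    ``t_offset``; spike delivery to postsynaptic conductances happens on the
    step after emission.
    """
    n_steps = round(duration / dt)
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be a multiple of dt")
    cells = network.cells
    classes = network.classes
    if state is None:
        state = resting_state(network)

    g_decay = np.exp(-dt / np.array([c.tau_syn for c in classes]))
    ca_decay = np.exp(-dt / cells.tau_ca)
    dg = np.array([c.dg for c in classes])
    projs = [
        (_contiguous_slice(p.pre), _contiguous_slice(p.post),
         p.class_index, p.w, dg[p.class_index])
        for p in network.projections
    ]
    ff = network.feedforward
    ff_pre = _contiguous_slice(ff.pre)
    ff_post = _contiguous_slice(ff.post)

    ids_chunks: list[np.ndarray] = []
    step_chunks: list[np.ndarray] = []
    prev_spikes = np.zeros(network.n, dtype=bool)

    for k in range(n_steps):
        conductance_step(state, classes, dt, _decay=g_decay)
        adaptation_step(state, cells, dt, _decay=ca_decay)
        if prev_spikes.any():
            for pre_sl, post_sl, cls_idx, w, scale in projs:
                active = np.flatnonzero(prev_spikes[pre_sl])
                if active.size:
                    state.g[post_sl, cls_idx] += scale * w[:, active].sum(axis=1)
        spikes = membrane_step(state, cells, classes, i_ext, dt, rng)
        apply_reset(state, cells, spikes)
        if plasticity is not None:
            plasticity.step(spikes[ff_pre], spikes[ff_post], dt)
        if spikes.any():
            ids = np.flatnonzero(spikes)
            ids_chunks.append(ids)
            step_chunks.append(np.full(ids.size, k))
        state.t += dt
        prev_spikes = spikes

    if ids_chunks:
        neuron_ids = np.concatenate(ids_chunks)
        times = t_offset + (np.concatenate(step_chunks) + 1) * dt
    else:
        neuron_ids = np.zeros(0, dtype=int)
        times = np.zeros(0)
    return neuron_ids, times, state
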