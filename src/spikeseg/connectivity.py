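"""Network construction: layer geometry and fixed connectivity.

The model is a two-layer network of excitatory (principal) cells, each layer
with its own private pool of inhibitory interneurons:

* input layer: principal cells on a 1-D ring with a Gaussian ("Mexican hat"
  excitatory arm) lateral weight profile under periodic boundaries;
* output layer: principal cells on a grid with *no* lateral excitation;
* within each layer, spatially uniform principal->interneuron and
  interneuron->principal coupling supplies the long-range inhibitory arm;
* between layers, full feed-forward excitatory connectivity with weights
  drawn uniformly from [0, 1] — the only plastic projection.

All neurons of the network share one global index space, ordered
[input E, input I, output E, output I]; every projection stores a dense
(post x pre) dimensionless weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    CellParams,
    ExperimentConfig,
    LayerSpec,
    SYNAPSE_CLASSES,
    SynapseClassParams,
)

__all__ = [
    "periodic_distance",
    "lateral_weight",
    "lateral_weight_matrix",
    "Projection",
    "CellArrays",
    "Network",
    "build_network",
]


def periodic_distance(i, j, dims):
    """Euclidean distance between neuron indices under periodic boundaries.

    ``dims`` is the layer shape: a 1-tuple makes the layer a ring, a 2-tuple
    a torus (row-major linear indices).  Per dimension the wrapped offset
    ``min(|di|, L - |di|)`` is used, so the distance never exceeds half the
    layer diagonal.  ``i`` and ``j`` may be scalars or arrays (broadcast).
    """
    dims = tuple(int(d) for d in dims)
    i = np.asarray(i)
    j = np.asarray(j)
    n_total = int(np.prod(dims))
    if np.any(i < 0) or np.any(i >= n_total) or np.any(j < 0) or np.any(j >= n_total):
        raise IndexError("neuron index out of range for layer dims")
    if len(dims) == 1:
        delta = np.abs(i - j)
        return np.minimum(delta, dims[0] - delta).astype(float)
    rows, cols = dims
    ri, ci = np.divmod(i, cols)
    rj, cj = np.divmod(j, cols)
    dr = np.abs(ri - rj)
    dc = np.abs(ci - cj)
    dr = np.minimum(dr, rows - dr)
    dc = np.minimum(dc, cols - dc)
    return np.hypot(dr, dc)


def lateral_weight(d, sigma_lat: float, w_lat_max: float = 1.0):
    """Gaussian lateral weight profile ``w_max * exp(-d^2 / (2 sigma^2))``.

    ``sigma_lat = 0`` degenerates to a delta profile: ``w_lat_max`` at
    ``d = 0`` and zero elsewhere.
    """
    d = np.asarray(d, dtype=float)
    if sigma_lat < 0:
        raise ValueError("sigma_lat must be non-negative")
    if sigma_lat == 0:
        return np.where(d == 0, w_lat_max, 0.0)
    return w_lat_max * np.exp(-(d ** 2) / (2.0 * sigma_lat ** 2))


def lateral_weight_matrix(spec: LayerSpec, rng: np.random.Generator,
                          flat_profile: bool = False) -> np.ndarray:
    """Symmetric lateral E->E weight matrix for one layer.

    Weights follow the Gaussian profile out to ``spec.radius`` and are zero
    beyond it and on the diagonal (no self-synapses).  With ``p_lateral`` <
    1 connections are dropped symmetrically.  ``flat_profile`` replaces the
    Gaussian by a constant equal to the *mean* retained Gaussian weight, so
    total lateral drive is preserved while the distance gradient — the
    feature under ablation — is removed.
    """
    n = spec.n_exc
    idx = np.arange(n)
    d = periodic_distance(idx[:, None], idx[None, :], spec.dims)
    w = lateral_weight(d, spec.sigma_lat, spec.w_lat_max)
    mask = (d <= spec.radius)
    np.fill_diagonal(mask, False)
    if spec.p_lateral < 1.0:
        keep = rng.random((n, n)) < spec.p_lateral
        keep = np.triu(keep, 1)
        keep = keep | keep.T
        mask &= keep
    w = np.where(mask, w, 0.0)
    if flat_profile:
        retained = w[mask]
        flat = retained.mean() if retained.size else 0.0
        w = np.where(mask, flat, 0.0)
    return w


@dataclass
class Projection:
    """A bundle of synapses of one class between two cell groups.

    ``pre`` and ``post`` are global index arrays; ``w`` is the (post x pre)
    dimensionless weight matrix in [0, w_max]; the conductance delivered by
    one presynaptic spike is ``w * dg`` nS where ``dg`` belongs to the
    synapse class.  Only the excitatory feed-forward projection is plastic.
    """

    pre: np.ndarray
    post: np.ndarray
    class_label: str
    w: np.ndarray
    plastic: bool = False

    def __post_init__(self) -> None:
        if self.w.shape != (len(self.post), len(self.pre)):
            raise ValueError("weight matrix shape must be (n_post, n_pre)")

    @property
    def class_index(self) -> int:
        return SYNAPSE_CLASSES.index(self.class_label)


@dataclass
class CellArrays:
    """Per-neuron somatic parameter vectors for the whole network."""

    c_m: np.ndarray
    g_leak: np.ndarray
    e_rest: np.ndarray
    v_thresh: np.ndarray
    v_reset: np.ndarray
    t_ref: np.ndarray
    e_k: np.ndarray
    tau_ca: np.ndarray
    dg_ahp: np.ndarray
    sigma_noise: np.ndarray  # mV per sqrt(ms)
    is_exc: np.ndarray  # boolean

    @property
    def n(self) -> int:
        return self.c_m.size


@dataclass
class Network:
    """The assembled two-layer network.

    Slices address the four cell groups in the global index space.  The
    feed-forward projection is exposed separately because the learning rule
    and the before/after weight comparisons operate on it.
    """

    cells: CellArrays
    classes: list[SynapseClassParams]
    projections: list[Projection]
    input_exc: slice
    input_inh: slice
    output_exc: slice
    output_inh: slice
    config: ExperimentConfig = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.cells.n

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def feedforward(self) -> Projection:
        for proj in self.projections:
            if proj.plastic:
                return proj
        raise LookupError("network has no plastic feed-forward projection")


def _fill_cells(arrs: dict, sl: slice, p: CellParams, is_exc: bool,
                no_adaptation: bool) -> None:
    arrs["c_m"][sl] = p.c_m
    arrs["g_leak"][sl] = p.g_leak
    arrs["e_rest"][sl] = p.e_rest
    arrs["v_thresh"][sl] = p.v_thresh
    arrs["v_reset"][sl] = p.v_reset
    arrs["t_ref"][sl] = p.t_ref
    arrs["e_k"][sl] = p.e_k
    arrs["tau_ca"][sl] = p.tau_ca
    arrs["dg_ahp"][sl] = 0.0 if (no_adaptation or not is_exc) else p.dg_ahp
    arrs["sigma_noise"][sl] = p.sigma_noise
    arrs["is_exc"][sl] = is_exc


def _uniform_projection(pre: np.ndarray, post: np.ndarray, label: str,
                        weight: float, p_connect: float,
                        rng: np.random.Generator) -> Projection:
    w = np.full((len(post), len(pre)), weight)
    if p_connect < 1.0:
        w *= rng.random(w.shape) < p_connect
    return Projection(pre=pre, post=post, class_label=label, w=w)


def build_network(config: ExperimentConfig,
                  rng: np.random.Generator | None = None) -> Network:
    """Assemble layers and projections from an experiment configuration.

    ``rng`` drives the random structural draws: the initial uniform [0, 1]
    feed-forward weights and any probabilistic connection masks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seeds.initialization)
    lin, lout = config.input_layer, config.output_layer
    counts = [lin.n_exc, lin.n_inh, lout.n_exc, lout.n_inh]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    in_e = slice(int(offsets[0]), int(offsets[1]))
    in_i = slice(int(offsets[1]), int(offsets[2]))
    out_e = slice(int(offsets[2]), int(offsets[3]))
    out_i = slice(int(offsets[3]), int(offsets[4]))
    n = int(offsets[4])

    arrs = {k: np.zeros(n) for k in
            ("c_m", "g_leak", "e_rest", "v_thresh", "v_reset", "t_ref",
             "e_k", "tau_ca", "dg_ahp", "sigma_noise")}
    arrs["is_exc"] = np.zeros(n, dtype=bool)
    noadapt = config.ablations.no_adaptation
    _fill_cells(arrs, in_e, config.cells_exc, True, noadapt)
    _fill_cells(arrs, in_i, config.cells_inh, False, noadapt)
    _fill_cells(arrs, out_e, config.cells_exc, True, noadapt)
    _fill_cells(arrs, out_i, config.cells_inh, False, noadapt)
    cells = CellArrays(**arrs)

    gidx = np.arange(n)
    projections: list[Projection] = []

    # Feed-forward plastic E -> E, full by default, uniform [0, 1] weights.
    w_ff = rng.uniform(0.0, 1.0, size=(lout.n_exc, lin.n_exc))
    if lin.p_feedforward < 1.0:
        w_ff *= rng.random(w_ff.shape) < lin.p_feedforward
    projections.append(Projection(pre=gidx[in_e], post=gidx[out_e],
                                  class_label="exc_feedforward", w=w_ff,
                                  plastic=True))

    # Lateral E -> E inside each layer (output layer has none).
    for sl, spec in ((in_e, lin), (out_e, lout)):
        if not spec.has_lateral_exc or config.ablations.no_lateral_ee:
            continue
        w_lat = lateral_weight_matrix(
            spec, rng, flat_profile=config.ablations.flat_lateral_profile)
        projections.append(Projection(pre=gidx[sl], post=gidx[sl],
                                      class_label="exc_lateral", w=w_lat))

    # Uniform excitatory <-> inhibitory loops, private to each layer.
    for e_sl, i_sl, spec in ((in_e, in_i, lin), (out_e, out_i, lout)):
        projections.append(_uniform_projection(
            gidx[e_sl], gidx[i_sl], "exc_to_inh", spec.w_exc_inh,
            spec.p_exc_inh, rng))
        projections.append(_uniform_projection(
            gidx[i_sl], gidx[e_sl], "inh_to_exc", spec.w_inh_exc,
            spec.p_inh_exc, rng))
        if spec.w_inh_inh > 0:
            projections.append(_uniform_projection(
                gidx[i_sl], gidx[i_sl], "inh_to_inh", spec.w_inh_inh,
                spec.p_inh_inh, rng))

    classes = [config.synapses[label] for label in SYNAPSE_CLASSES]
    return Network(cells=cells, classes=classes, projections=projections,
                   input_exc=in_e, input_inh=in_i, output_exc=out_e,
                   output_inh=out_i, config=config)
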