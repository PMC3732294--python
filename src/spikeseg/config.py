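"""Parameter containers and experiment configuration.

All quantities carry the units used throughout the simulator: potentials in
mV, conductances in nS, capacitances in pF, currents in nA, times in ms.
With these units ``I/C`` integrates directly to mV/ms (1 pA / 1 pF =
1 mV/ms), so no hidden conversion factors appear in the dynamics code.

Defaults are the published cortical integrate-and-fire constants this model
family uses (500 pF / 25 nS excitatory soma, 2 ms AMPA-like and 5 ms
GABA-like conductance decay, 6 nS per-spike adaptation increment with a
50 ms calcium decay, and the 15/25 ms STDP trace constants with learning
rate 0.1).  Where a constant was tuned rather than measured (uniform
excitatory<->inhibitory coupling, peak lateral weight, membrane-noise
fraction) the tuned default is exposed here and discussed in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "CellParams",
    "SynapseClassParams",
    "STDPParams",
    "LayerSpec",
    "StimulusSpec",
    "Schedule",
    "Ablations",
    "Seeds",
    "ExperimentConfig",
    "SYNAPSE_CLASSES",
    "default_config",
    "scaled_two_stimulus_config",
    "scaled_four_stimulus_config",
    "load_config",
    "save_config",
]


@dataclass
class CellParams:
    """Somatic parameters of one cell population (excitatory or inhibitory).

    ``v_reset`` is the after-spike hyperpolarization potential.  For the
    excitatory population it sits 4 mV below threshold; the membrane is held
    there for the absolute refractory period ``t_ref``.  ``noise_frac``
    scales the membrane Wiener noise: the per-sqrt(ms) standard deviation is
    ``noise_frac * (v_thresh - v_reset)``.
    """

    c_m: float  # capacitance, pF
    g_leak: float  # leak conductance, nS
    e_rest: float  # resting potential, mV
    v_thresh: float  # firing threshold, mV
    v_reset: float  # after-spike hyperpolarization potential, mV
    t_ref: float = 2.0  # absolute refractory period, ms
    e_k: float = -80.0  # potassium reversal (adaptation current), mV
    tau_ca: float = 50.0  # calcium / adaptation decay constant, ms
    dg_ahp: float = 6.0  # per-spike adaptation conductance increment, nS
    noise_frac: float = 0.02  # noise s.d. as fraction of (v_thresh - v_reset)

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.g_leak <= 0:
            raise ValueError("c_m and g_leak must be positive")
        if self.e_rest >= self.v_thresh:
            raise ValueError("e_rest must lie below v_thresh")
        if self.t_ref < 0 or self.tau_ca <= 0 or self.dg_ahp < 0:
            raise ValueError("invalid refractory/adaptation parameters")
        # Only cells with an adaptation current need a hyperpolarizing E_K;
        # interneurons (dg_ahp = 0) may rest below it.
        if self.dg_ahp > 0 and self.e_k > self.e_rest:
            raise ValueError("e_k must not exceed e_rest for adapting cells")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_leak, ms."""
        return self.c_m / self.g_leak

    @property
    def sigma_noise(self) -> float:
        """Membrane noise standard deviation, mV per sqrt(ms)."""
        return self.noise_frac * (self.v_thresh - self.v_reset)


def excitatory_cell_defaults() -> CellParams:
    return CellParams(c_m=500.0, g_leak=25.0, e_rest=-74.0,
                      v_thresh=-53.0, v_reset=-57.0, dg_ahp=6.0)


def inhibitory_cell_defaults() -> CellParams:
    # Interneurons carry no adaptation current (dg_ahp = 0).
    return CellParams(c_m=214.0, g_leak=18.0, e_rest=-82.0,
                      v_thresh=-53.0, v_reset=-58.0, dg_ahp=0.0)


@dataclass
class SynapseClassParams:
    """One synapse class: reversal potential, decay constant and scaling.

    ``dg`` is the biological scaling constant: a presynaptic spike through a
    synapse of dimensionless weight w increments the postsynaptic class
    conductance by ``w * dg`` nS.
    """

    class_label: str
    e_rev: float  # reversal potential, mV
    tau_syn: float  # conductance decay constant, ms
    dg: float  # conductance per unit weight, nS

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.dg < 0:
            raise ValueError("dg must be non-negative")


#: Canonical ordering of the five synapse classes; the conductance matrix in
#: :class:`spikeseg.dynamics.NetworkState` has one column per entry.
SYNAPSE_CLASSES = (
    "exc_feedforward",
    "exc_lateral",
    "exc_to_inh",
    "inh_to_exc",
    "inh_to_inh",
)


def synapse_class_defaults() -> dict[str, SynapseClassParams]:
    """Default synaptic parameters.

    The plastic feed-forward scaling of 3.75 nS makes the product
    ``w * dg`` span the [0, 3.75] nS conductance range for w in [0, 1];
    fixed classes use the 5.0 nS per-unit-weight scaling.
    """
    return {
        "exc_feedforward": SynapseClassParams("exc_feedforward", 0.0, 2.0, 3.75),
        "exc_lateral": SynapseClassParams("exc_lateral", 0.0, 2.0, 5.0),
        "exc_to_inh": SynapseClassParams("exc_to_inh", 0.0, 2.0, 5.0),
        "inh_to_exc": SynapseClassParams("inh_to_exc", -70.0, 5.0, 5.0),
        "inh_to_inh": SynapseClassParams("inh_to_inh", -70.0, 5.0, 5.0),
    }


@dataclass
class LayerSpec:
    """Geometry and fixed-coupling parameters for one layer.

    ``dims`` is a single length (ring) or a (rows, cols) pair (torus) for
    the excitatory sheet.  ``sigma_lat`` and ``lateral_radius`` shape the
    Gaussian lateral excitatory profile; ``w_lat_max`` is its peak
    dimensionless weight.  ``w_exc_inh`` / ``w_inh_exc`` / ``w_inh_inh`` are
    the spatially uniform weights of the interneuron loop (the long-range
    inhibitory arm of the Mexican hat).  ``p_*`` are per-class connection
    probabilities.
    """

    n_exc: int
    n_inh: int
    dims: tuple[int, ...] = ()
    sigma_lat: float = 32.0
    lateral_radius: float | None = None  # None -> half the layer extent
    w_lat_max: float = 1.0
    has_lateral_exc: bool = True
    w_exc_inh: float = 0.2
    w_inh_exc: float = 1.0
    w_inh_inh: float = 0.0
    p_feedforward: float = 1.0
    p_lateral: float = 1.0
    p_exc_inh: float = 1.0
    p_inh_exc: float = 1.0
    p_inh_inh: float = 1.0

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("layer populations must be non-empty")
        if not self.dims:
            self.dims = (self.n_exc,)
        self.dims = tuple(int(x) for x in self.dims)
        n_from_dims = self.dims[0] if len(self.dims) == 1 else self.dims[0] * self.dims[1]
        if n_from_dims != self.n_exc:
            raise ValueError("dims inconsistent with n_exc")
        if self.sigma_lat < 0:
            raise ValueError("sigma_lat must be non-negative")
        for p in (self.p_feedforward, self.p_lateral, self.p_exc_inh,
                  self.p_inh_exc, self.p_inh_inh):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must be in [0, 1]")

    @property
    def radius(self) -> float:
        if self.lateral_radius is not None:
            return self.lateral_radius
        return max(self.dims) / 2.0


@dataclass
class STDPParams:
    """Trace-based multiplicative STDP parameters.

    ``a_pre`` is the saturating per-spike increment of the presynaptic
    (glutamate) trace, ``a_post`` of the postsynaptic (NMDA-unblocking)
    trace.  ``mode`` selects the fully multiplicative rule (LTP soft-bounded
    by ``w_max - w``, LTD by ``w``) or a mixed variant with additive LTP.
    """

    tau_pre: float = 15.0  # ms
    tau_post: float = 25.0  # ms
    a_pre: float = 0.5
    a_post: float = 0.5
    eta: float = 0.1
    w_min: float = 0.0
    w_max: float = 1.0
    mode: str = "multiplicative"  # or "additive_ltp"

    def __post_init__(self) -> None:
        if self.tau_pre <= 0 or self.tau_post <= 0:
            raise ValueError("trace time constants must be positive")
        if not (0 < self.a_pre <= 1 and 0 < self.a_post <= 1):
            raise ValueError("trace increments must lie in (0, 1]")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.mode not in ("multiplicative", "additive_ltp"):
            raise ValueError(f"unknown STDP mode {self.mode!r}")


@dataclass
class StimulusSpec:
    """A translating stimulus: a contiguous block of input neurons.

    Transform k activates indices ``[pool_start + k*shift,
    pool_start + k*shift + width)``.  ``shift < width`` so consecutive
    transforms overlap, which is what lets continuous-transformation
    learning bind them onto common output cells.
    """

    stim_id: int
    pool_start: int
    pool_end: int
    width: int
    n_transforms: int
    shift: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_transforms <= 0 or self.shift <= 0:
            raise ValueError("width, n_transforms and shift must be positive")
        if self.shift >= self.width:
            raise ValueError("shift must be smaller than width (transforms must overlap)")
        last_end = self.pool_start + (self.n_transforms - 1) * self.shift + self.width
        if last_end > self.pool_end:
            raise ValueError(
                f"stimulus {self.stim_id}: transforms exceed pool "
                f"[{self.pool_start}, {self.pool_end})"
            )

    @property
    def overlap_fraction(self) -> float:
        """Fraction of neurons shared by consecutive transforms."""
        return (self.width - self.shift) / self.width


@dataclass
class Schedule:
    """Presentation schedule: pretest -> train (x epochs) -> posttest."""

    cue_current: float = 0.75  # nA injected into cue-driven input neurons
    cue_period_train: float = 500.0  # ms per transform during training
    cue_period_test: float = 500.0  # ms per transform during testing
    n_epochs: int = 10
    direction_policy: str = "per_epoch"  # or "per_step"

    def __post_init__(self) -> None:
        if self.cue_period_train <= 0 or self.cue_period_test <= 0:
            raise ValueError("cue periods must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")
        if self.direction_policy not in ("per_epoch", "per_step"):
            raise ValueError(f"unknown direction policy {self.direction_policy!r}")


@dataclass
class Ablations:
    no_lateral_ee: bool = False
    flat_lateral_profile: bool = False
    no_adaptation: bool = False


@dataclass
class Seeds:
    simulation: int = 0
    initialization: int = 1


@dataclass
class ExperimentConfig:
    """Everything needed to build the network and run one experiment."""

    input_layer: LayerSpec
    output_layer: LayerSpec
    cells_exc: CellParams = field(default_factory=excitatory_cell_defaults)
    cells_inh: CellParams = field(default_factory=inhibitory_cell_defaults)
    synapses: dict[str, SynapseClassParams] = field(default_factory=synapse_class_defaults)
    stdp: STDPParams = field(default_factory=STDPParams)
    stimuli: list[StimulusSpec] = field(default_factory=list)
    schedule: Schedule = field(default_factory=Schedule)
    ablations: Ablations = field(default_factory=Ablations)
    seeds: Seeds = field(default_factory=Seeds)
    dt: float = 0.02  # ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for stim in self.stimuli:
            if stim.pool_end > self.input_layer.n_exc or stim.pool_start < 0:
                raise ValueError(
                    f"stimulus {stim.stim_id} pool exceeds input layer bounds"
                )


def _two_stimulus_specs(n_input: int, width: int, shift: int,
                        n_transforms: int) -> list[StimulusSpec]:
    half = n_input // 2
    return [
        StimulusSpec(0, 0, half, width, n_transforms, shift),
        StimulusSpec(1, half, n_input, width, n_transforms, shift),
    ]


def default_config() -> ExperimentConfig:
    """Full-scale two-stimulus configuration.

    512 + 128 input cells on a ring, 256 + 64 output cells on a 16 x 16
    grid with no lateral excitation, two 64-wide stimuli each owning half
    the input ring, 13 transforms with a 16-neuron shift (75% overlap),
    500 ms cue periods and 10 training epochs.
    """
    return ExperimentConfig(
        input_layer=LayerSpec(n_exc=512, n_inh=128, dims=(512,), sigma_lat=32.0),
        output_layer=LayerSpec(n_exc=256, n_inh=64, dims=(16, 16),
                               has_lateral_exc=False),
        stimuli=_two_stimulus_specs(512, width=64, shift=16, n_transforms=13),
        schedule=Schedule(),
        dt=0.02,
    )


def scaled_two_stimulus_config(sim_seed: int = 0, init_seed: int = 1) -> ExperimentConfig:
    """Half-scale two-stimulus configuration used by the fast experiments.

    256 + 64 input cells, 64 + 16 output cells, two 32-wide stimuli with an
    8-neuron shift (the same 75% overlap and 13 transforms as the
    full-scale run), 250 ms cue periods, 5 epochs, dt = 0.05 ms.
    sigma_lat keeps the optimal ratio of half the stimulus width.
    """
    return ExperimentConfig(
        input_layer=LayerSpec(n_exc=256, n_inh=64, dims=(256,), sigma_lat=16.0),
        output_layer=LayerSpec(n_exc=64, n_inh=16, dims=(8, 8),
                               has_lateral_exc=False),
        stimuli=_two_stimulus_specs(256, width=32, shift=8, n_transforms=13),
        schedule=Schedule(cue_period_train=250.0, cue_period_test=250.0, n_epochs=5),
        seeds=Seeds(simulation=sim_seed, initialization=init_seed),
        dt=0.05,
    )


def scaled_four_stimulus_config(sim_seed: int = 0, init_seed: int = 1,
                                n_epochs: int = 16) -> ExperimentConfig:
    """Half-scale four-stimulus (capacity) configuration.

    Four 16-wide stimuli in quarter pools of the 256-cell input ring with a
    4-neuron shift (75% overlap, 13 transforms tiling each pool exactly).
    Following the capacity protocol the lateral spread is reduced to half
    the (smaller) stimulus width and the cue current is reduced to slow the
    firing; training is extended beyond the two-stimulus epoch count.  At
    this scale the output volleys carry half as many spikes, so the
    output-layer interneuron loop is proportionally strengthened to keep
    per-volley competition effective, membrane noise is raised to keep the
    transient coalitions between stimulus pools reshuffling, and testing
    windows are lengthened to resolve the sparser output rates.
    """
    quarter = 256 // 4
    stimuli = [
        StimulusSpec(k, k * quarter, (k + 1) * quarter, width=16,
                     n_transforms=13, shift=4)
        for k in range(4)
    ]
    cells_exc = excitatory_cell_defaults()
    cells_exc.noise_frac = 0.05
    return ExperimentConfig(
        input_layer=LayerSpec(n_exc=256, n_inh=64, dims=(256,), sigma_lat=8.0),
        output_layer=LayerSpec(n_exc=64, n_inh=16, dims=(8, 8),
                               has_lateral_exc=False,
                               w_exc_inh=2.0, w_inh_exc=2.0),
        cells_exc=cells_exc,
        stimuli=stimuli,
        schedule=Schedule(cue_current=0.6, cue_period_train=250.0,
                          cue_period_test=500.0, n_epochs=n_epochs),
        seeds=Seeds(simulation=sim_seed, initialization=init_seed),
        dt=0.05,
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def _config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["input_layer"]["dims"] = list(d["input_layer"]["dims"])
    d["output_layer"]["dims"] = list(d["output_layer"]["dims"])
    return d


def save_config(cfg: ExperimentConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def config_from_dict(d: dict) -> ExperimentConfig:
    def layer(sub: dict) -> LayerSpec:
        sub = dict(sub)
        sub["dims"] = tuple(sub.get("dims") or ())
        return LayerSpec(**sub)

    synapses = {
        name: SynapseClassParams(**params)
        for name, params in d.get("synapses", {}).items()
    } or synapse_class_defaults()
    return ExperimentConfig(
        input_layer=layer(d["input_layer"]),
        output_layer=layer(d["output_layer"]),
        cells_exc=CellParams(**d.get("cells_exc", {})) if d.get("cells_exc")
        else excitatory_cell_defaults(),
        cells_inh=CellParams(**d.get("cells_inh", {})) if d.get("cells_inh")
        else inhibitory_cell_defaults(),
        synapses=synapses,
        stdp=STDPParams(**d.get("stdp", {})),
        stimuli=[StimulusSpec(**s) for s in d.get("stimuli", [])],
        schedule=Schedule(**d.get("schedule", {})),
        ablations=Ablations(**d.get("ablations", {})),
        seeds=Seeds(**d.get("seeds", {})),
        dt=d.get("dt", 0.02),
    )
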