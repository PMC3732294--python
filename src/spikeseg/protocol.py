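"""Stimulus generation and the pretest -> train -> posttest protocol.

Stimuli are abstract, homogeneous patches: contiguous blocks of input-layer
principal cells receiving a tonic cue current.  A translating stimulus is a
sequence of such blocks (transforms) shifted by fewer neurons than the block
width, so consecutive transforms overlap and continuous-transformation
learning can bind them onto common output cells.

During *testing* every transform of every stimulus is presented alone, with
plasticity frozen and the dynamic state reset between presentations so no
presentation contaminates the next.  During *training* all stimuli are
presented simultaneously, translating in lock-step (same direction, same
rate); the sweep direction is drawn at random once per epoch and plasticity
is active on the feed-forward projection only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .config import ExperimentConfig, Schedule, StimulusSpec
from .connectivity import Network, build_network
from .dynamics import NetworkState, resting_state, simulate_window
from .plasticity import OnlinePlasticity

__all__ = [
    "Interval",
    "SpikeRecord",
    "make_transforms",
    "run_testing_phase",
    "run_training_phase",
    "run_static_presentation",
    "ExperimentResult",
    "run_experiment",
    "sweep",
]


@dataclass
class Interval:
    """One annotated presentation interval of a phase.

    ``stimulus`` is the stimulus id during testing, or -1 during training
    (all stimuli are on simultaneously); ``transform`` is the common
    transform index.
    """

    t_start: float
    t_end: float
    phase: str
    stimulus: int
    transform: int


@dataclass
class SpikeRecord:
    """All spike events of one phase, with presentation annotations."""

    neuron_ids: np.ndarray
    times: np.ndarray
    intervals: list[Interval] = field(default_factory=list)
    phase: str = ""

    def events_in(self, t_start: float, t_end: float):
        """Return (ids, times) of events with t_start < t <= t_end."""
        lo = np.searchsorted(self.times, t_start, side="right")
        hi = np.searchsorted(self.times, t_end, side="right")
        return self.neuron_ids[lo:hi], self.times[lo:hi]

    @property
    def duration(self) -> float:
        return max((iv.t_end for iv in self.intervals), default=0.0)

    def to_dataframe(self) -> pd.DataFrame:
        """Delimited-text-friendly view: one row per spike with annotations."""
        phase = np.empty(self.times.size, dtype=object)
        stim = np.full(self.times.size, -1)
        transform = np.full(self.times.size, -1)
        phase[:] = self.phase
        for iv in self.intervals:
            lo = np.searchsorted(self.times, iv.t_start, side="right")
            hi = np.searchsorted(self.times, iv.t_end, side="right")
            stim[lo:hi] = iv.stimulus
            transform[lo:hi] = iv.transform
        return pd.DataFrame({
            "neuron_id": self.neuron_ids,
            "time_ms": self.times,
            "phase": phase,
            "stimulus": stim,
            "transform": transform,
        })

    def save(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def make_transforms(spec: StimulusSpec) -> list[np.ndarray]:
    """Active input-neuron index sets for every transform of a stimulus."""
    transforms = []
    for k in range(spec.n_transforms):
        start = spec.pool_start + k * spec.shift
        end = start + spec.width
        if end > spec.pool_end:
            raise ValueError(
                f"transform {k} of stimulus {spec.stim_id} exceeds its pool")
        transforms.append(np.arange(start, end))
    return transforms


def _cue_vector(network: Network, active: np.ndarray, current: float) -> np.ndarray:
    i_ext = np.zeros(network.n)
    i_ext[active] = current
    return i_ext


def run_testing_phase(network: Network, stimuli: list[StimulusSpec],
                      schedule: Schedule, dt: float,
                      rng: np.random.Generator, phase: str = "test") -> SpikeRecord:
    """Present every transform of every stimulus alone, plasticity off.

    The dynamic state is fully reset before each presentation, so the
    response to one transform cannot contaminate the next.
    """
    ids_all, times_all, intervals = [], [], []
    t = 0.0
    for spec in stimuli:
        for k, active in enumerate(make_transforms(spec)):
            state = resting_state(network)
            i_ext = _cue_vector(network, active, schedule.cue_current)
            ids, times, _ = simulate_window(
                network, i_ext, schedule.cue_period_test, dt, rng,
                state=state, t_offset=t)
            ids_all.append(ids)
            times_all.append(times)
            intervals.append(Interval(t, t + schedule.cue_period_test, phase,
                                      spec.stim_id, k))
            t += schedule.cue_period_test
    return SpikeRecord(np.concatenate(ids_all), np.concatenate(times_all),
                       intervals, phase)


def run_training_phase(network: Network, stimuli: list[StimulusSpec],
                       schedule: Schedule, dt: float,
                       rng: np.random.Generator,
                       plasticity: OnlinePlasticity):
    """Train with all stimuli on simultaneously, translating in lock-step.

    Each epoch visits all transforms once, in ascending or descending order
    according to a direction drawn per epoch (``per_epoch`` policy) or per
    transform step (``per_step``, a random walk over transform indices).
    The dynamic state persists across transform steps and epochs; weights
    are snapshot after every epoch.  Returns (record, snapshots).
    """
    n_transforms = stimuli[0].n_transforms
    if any(s.n_transforms != n_transforms for s in stimuli):
        raise ValueError("lock-step training requires equal transform counts")
    transform_sets = [make_transforms(s) for s in stimuli]

    state = resting_state(network)
    plasticity.reset()
    ids_all, times_all, intervals = [], [], []
    snapshots = []
    t = 0.0
    pos = 0
    for _ in range(schedule.n_epochs):
        if schedule.direction_policy == "per_epoch":
            ascending = bool(rng.integers(0, 2))
            order = range(n_transforms) if ascending else range(n_transforms - 1, -1, -1)
        else:  # random walk visiting n_transforms steps
            order = []
            for _step in range(n_transforms):
                pos = (pos + (1 if rng.integers(0, 2) else -1)) % n_transforms
                order.append(pos)
        for k in order:
            active = np.concatenate([ts[k] for ts in transform_sets])
            i_ext = _cue_vector(network, active, schedule.cue_current)
            ids, times, state = simulate_window(
                network, i_ext, schedule.cue_period_train, dt, rng,
                state=state, plasticity=plasticity, t_offset=t)
            ids_all.append(ids)
            times_all.append(times)
            intervals.append(Interval(t, t + schedule.cue_period_train,
                                      "train", -1, k))
            t += schedule.cue_period_train
        snapshots.append(network.feedforward.w.copy())
    record = SpikeRecord(np.concatenate(ids_all), np.concatenate(times_all),
                         intervals, "train")
    return record, snapshots


def run_static_presentation(network: Network, stimuli: list[StimulusSpec],
                            transform: int, duration: float,
                            cue_current: float, dt: float,
                            rng: np.random.Generator) -> SpikeRecord:
    """Present all stimuli simultaneously at one fixed transform.

    Used to probe the input-layer dynamics (anti-phase oscillations)
    without plasticity or translation.
    """
    active = np.concatenate([make_transforms(s)[transform] for s in stimuli])
    i_ext = _cue_vector(network, active, cue_current)
    ids, times, _ = simulate_window(network, i_ext, duration, dt, rng)
    return SpikeRecord(ids, times,
                       [Interval(0.0, duration, "static", -1, transform)],
                       "static")


@dataclass
class ExperimentResult:
    """Everything a single pretest/train/posttest run produces."""

    config: ExperimentConfig
    network: Network
    pretest: SpikeRecord
    posttest: SpikeRecord
    training: SpikeRecord
    w_initial: np.ndarray
    w_final: np.ndarray
    w_snapshots: list[np.ndarray]
    rates_pre: analysis.RateTable
    rates_post: analysis.RateTable
    info_pre: analysis.InfoResult
    info_post: analysis.InfoResult


def _phase_rngs(sim_seed: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(sim_seed).spawn(3)
    return [np.random.default_rng(s) for s in seqs]


def run_experiment(config: ExperimentConfig, max_cells: int = 5,
                   keep_training_record: bool = True) -> ExperimentResult:
    """Run the full protocol and evaluate the information measures.

    Deterministic given the configuration seeds: the initialization seed
    drives the structural draws, and three independent streams derived from
    the simulation seed drive the pretest, training and posttest noise.
    """
    if not config.stimuli:
        raise ValueError("experiment requires at least one stimulus")
    rng_init = np.random.default_rng(config.seeds.initialization)
    network = build_network(config, rng_init)
    rng_pre, rng_train, rng_post = _phase_rngs(config.seeds.simulation)

    w_initial = network.feedforward.w.copy()
    pretest = run_testing_phase(network, config.stimuli, config.schedule,
                                config.dt, rng_pre, phase="pretest")
    plast = OnlinePlasticity(network.feedforward, config.stdp)
    training, snapshots = run_training_phase(
        network, config.stimuli, config.schedule, config.dt, rng_train, plast)
    posttest = run_testing_phase(network, config.stimuli, config.schedule,
                                 config.dt, rng_post, phase="posttest")
    w_final = network.feedforward.w.copy()

    rates_pre = analysis.compute_rates(pretest, network.output_exc)
    rates_post = analysis.compute_rates(posttest, network.output_exc)
    rng_info = np.random.default_rng(np.random.SeedSequence(
        entropy=[config.seeds.simulation, 0x1F]).generate_state(1)[0])
    info_pre = analysis.evaluate_information(
        rates_pre, max_cells=max_cells,
        rng=np.random.default_rng(rng_info.integers(2 ** 31)))
    info_post = analysis.evaluate_information(
        rates_post, max_cells=max_cells,
        rng=np.random.default_rng(rng_info.integers(2 ** 31)))

    if not keep_training_record:
        training = SpikeRecord(np.zeros(0, dtype=int), np.zeros(0), [], "train")
    return ExperimentResult(
        config=config, network=network, pretest=pretest, posttest=posttest,
        training=training, w_initial=w_initial, w_final=w_final,
        w_snapshots=snapshots, rates_pre=rates_pre, rates_post=rates_post,
        info_pre=info_pre, info_post=info_post)


_SWEEPABLE = ("sigma_lat", "stdp_tau_asymmetric", "stdp_tau_symmetric")


def _apply_sweep_value(config: ExperimentConfig, param: str, value: float) -> None:
    if param == "sigma_lat":
        config.input_layer.sigma_lat = float(value)
    elif param == "stdp_tau_asymmetric":
        # Keep the default tau_post / tau_pre = 25/15 ratio fixed.
        config.stdp.tau_pre = float(value)
        config.stdp.tau_post = float(value) * 25.0 / 15.0
    elif param == "stdp_tau_symmetric":
        config.stdp.tau_pre = float(value)
        config.stdp.tau_post = float(value)
    else:
        raise ValueError(f"parameter {param!r} is not sweepable; "
                         f"choose one of {_SWEEPABLE}")


def sweep(config: ExperimentConfig, param_name: str, values,
          n_seeds: int = 10, max_cells: int = 5) -> pd.DataFrame:
    """Run one full experiment per (value, seed) and score each run.

    Returns a tidy table with columns ``value``, ``seed`` and
    ``info_score`` (the fraction of output cells carrying near-maximal
    single-cell information for the least well represented stimulus);
    aggregate with ``summarize_sweep`` for the mean +/- SEM per value.
    """
    rows = []
    for value in values:
        for seed in range(n_seeds):
            cfg = copy.deepcopy(config)
            _apply_sweep_value(cfg, param_name, value)
            cfg.seeds.simulation = int(
                np.random.SeedSequence([config.seeds.simulation, seed]
                                       ).generate_state(1)[0] % (2 ** 31))
            cfg.seeds.initialization = int(
                np.random.SeedSequence([config.seeds.initialization, seed, 1]
                                       ).generate_state(1)[0] % (2 ** 31))
            result = run_experiment(cfg, max_cells=max_cells,
                                    keep_training_record=False)
            rows.append({"value": value, "seed": seed,
                         "info_score": result.info_post.info_score})
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby("value")["info_score"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem()}).reset_index()
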