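import numpy as np
import pytest

import spikeseg as ss


def single_neuron_config(adaptation: bool = True, noise: bool = True,
                         dt: float = 0.02) -> ss.ExperimentConfig:
    """A network holding one isolated excitatory cell (plus the minimal
    counterpart populations, all disconnected)."""
    cfg = ss.ExperimentConfig(
        input_layer=ss.LayerSpec(n_exc=1, n_inh=1, dims=(1,), sigma_lat=1.0,
                                 has_lateral_exc=False, w_exc_inh=0.0,
                                 w_inh_exc=0.0),
        output_layer=ss.LayerSpec(n_exc=1, n_inh=1, dims=(1,),
                                  has_lateral_exc=False, w_exc_inh=0.0,
                                  w_inh_exc=0.0),
        dt=dt,
    )
    if not adaptation:
        cfg.cells_exc.dg_ahp = 0.0
    if not noise:
        cfg.cells_exc.noise_frac = 0.0
        cfg.cells_inh.noise_frac = 0.0
    return cfg


@pytest.fixture
def isolated_neuron():
    """(network, drive) factory for a single excitatory cell."""

    def build(adaptation=True, noise=True, dt=0.02, current=0.75):
        cfg = single_neuron_config(adaptation=adaptation, noise=noise, dt=dt)
        net = ss.build_network(cfg, np.random.default_rng(0))
        i_ext = np.zeros(net.n)
        i_ext[0] = current
        return net, i_ext

    return build


def micro_config(n_epochs: int = 1, sim_seed: int = 0,
                 init_seed: int = 1) -> ss.ExperimentConfig:
    """A miniature but fully functional two-stimulus experiment, for fast
    protocol-level tests (determinism, bookkeeping, sweep mechanics)."""
    return ss.ExperimentConfig(
        input_layer=ss.LayerSpec(n_exc=32, n_inh=8, dims=(32,), sigma_lat=4.0),
        output_layer=ss.LayerSpec(n_exc=8, n_inh=2, dims=(8,),
                                  has_lateral_exc=False),
        stimuli=[
            ss.StimulusSpec(0, 0, 16, width=8, n_transforms=3, shift=4),
            ss.StimulusSpec(1, 16, 32, width=8, n_transforms=3, shift=4),
        ],
        schedule=ss.Schedule(cue_period_train=50.0, cue_period_test=50.0,
                             n_epochs=n_epochs),
        seeds=ss.Seeds(simulation=sim_seed, initialization=init_seed),
        dt=0.1,
    )


@pytest.fixture
def micro_experiment_config():
    return micro_config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
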