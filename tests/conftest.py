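import numpy as np
import pytest

from proxdec import design, simulate


@pytest.fixture(scope="session")
def tiny_params():
    """Smallest valid Experiment 1 design: quick to simulate, full structure."""
    return design.exp1_scaled_params(
        n_runs_main=2, trials_per_run=16,
        n_runs_training=2, miniblocks_per_training_run=8,
        localizer_miniblocks_per_run=4,
    )


@pytest.fixture(scope="session")
def tiny_params_exp2():
    return design.exp2_scaled_params(
        n_runs_main=3, trials_per_run=8,
        n_runs_training=2, miniblocks_per_training_run=8,
        localizer_miniblocks_per_run=4,
    )


@pytest.fixture(scope="session")
def tiny_meta():
    return simulate.make_voxel_meta(80)


@pytest.fixture(scope="session")
def tiny_subject(tiny_params, tiny_meta):
    tp = simulate.TruthParams(amp_shape=0.05, amp_background=0.02)
    return simulate.simulate_subject(tiny_params, tp, tiny_meta, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
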