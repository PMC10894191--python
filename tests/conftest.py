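import numpy as np
import pytest

import revlearn as rl
from revlearn.synth import VoxelSimConfig, gen_voxel_timeseries


@pytest.fixture(scope="session")
def default_schedule():
    return rl.generate_schedule(rl.TaskConfig(seed=11))


@pytest.fixture(scope="session")
def small_task_config():
    """Single short run: 32 trials, 3 reversals per cue."""
    return rl.TaskConfig(
        n_runs=1, trials_per_run=32, reversals_per_cue_per_run=3, seed=5
    )


@pytest.fixture(scope="session")
def small_schedule(small_task_config):
    return rl.generate_schedule(small_task_config)


@pytest.fixture(scope="session")
def small_behavior(small_schedule):
    return rl.simulate_agent(small_schedule, rl.AgentParams(0.9, 5.0), seed=7)


@pytest.fixture(scope="session")
def small_voxel_config():
    return VoxelSimConfig(dims=(8, 8, 6), n_vols_per_run=230, noise_sd=0.5)


@pytest.fixture(scope="session")
def small_voxel_dataset(small_voxel_config, small_schedule, small_behavior):
    return gen_voxel_timeseries(
        small_voxel_config, small_schedule, small_behavior, seed=13
    )
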