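import numpy as np
import pytest

from neurorig.demo import demo_rig, example_task_dict, gaussian_scene
from neurorig.taskengine import Manager


@pytest.fixture
def rig():
    return demo_rig(seed=0)


@pytest.fixture
def manager(rig):
    return Manager(rig, seed=1, scene=gaussian_scene())


@pytest.fixture
def worked_example_task():
    return example_task_dict()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
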