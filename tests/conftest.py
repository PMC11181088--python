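import numpy as np
import pytest

import poselight as pl
from poselight.rdm import normalize_rdm


@pytest.fixture(scope="session")
def poses60():
    records, canonical = pl.generate_poses(60, jitter_sd=0.1, seed=11)
    return records, canonical


@pytest.fixture(scope="session")
def model_rdms(poses60):
    records, _ = poses60
    return {m: normalize_rdm(pl.build_model_rdm(records, m)) for m in pl.POSE_MODELS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
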