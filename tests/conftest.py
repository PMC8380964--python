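import numpy as np
import pytest

from nethom.simulate import default_spec, generate_cohort
from nethom.types import BoldRun, NetworkMask


@pytest.fixture(scope="session")
def desk_cohort():
    """One default-scale cohort shared by read-only tests."""
    return generate_cohort(default_spec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_run(rng, shape=(4, 4, 3), t=60, tr=2.0, subject_id="s0"):
    data = rng.standard_normal((*shape, t))
    return BoldRun(subject_id, data, tr, np.eye(4))


def make_mask(shape=(4, 4, 3), frac=0.5, rng=None, affine=None):
    if rng is None:
        ind = np.ones(shape, dtype=bool)
    else:
        ind = rng.random(shape) < frac
        while ind.sum() < 2:
            ind = rng.random(shape) < frac
    return NetworkMask(ind, np.eye(4) if affine is None else affine)
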