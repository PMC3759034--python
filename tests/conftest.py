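import numpy as np
import pytest

from icarank import PhantomSpec, Volume4D


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 2-run phantom small enough for per-test pipeline stages."""
    return PhantomSpec(n_runs=2, seed=11)


def make_noise_volume(shape=(16, 16, 8), t=40, seed=0, tr=2.5) -> Volume4D:
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    return Volume4D(
        data=rng.standard_normal(shape + (t,)),
        voxel_size=(1.0, 1.0, 1.0),
        tr=tr,
        brain_mask=mask,
        run_boundaries=[0],
    )
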