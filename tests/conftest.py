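import numpy as np
import pytest

from phasebmd.phantom import PhantomSpec, generate_patient

# A small, fast spec reused across modules: 7 classifier levels + L3 so the
# lumbar BMD average (L1-L3) is fully available.
SMALL_LEVELS = ("T8", "T9", "T10", "T11", "T12", "L1", "L2", "L3")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        n_patients=4,
        vertebral_levels=SMALL_LEVELS,
        fov_size=(64, 64, 16 * len(SMALL_LEVELS)),
        fracture_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_patient(small_spec, 0)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(
        n_patients=6,
        vertebral_levels=SMALL_LEVELS,
        fov_size=(64, 64, 16 * len(SMALL_LEVELS)),
        noise_sd=0.0,
        fracture_rate=0.0,
        seed=23,
    )


@pytest.fixture(scope="session")
def noiseless_cases(noiseless_spec):
    return [generate_patient(noiseless_spec, i) for i in range(noiseless_spec.n_patients)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
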