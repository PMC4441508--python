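import numpy as np
import pytest

from rvlvcad.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def detector_model():
    """The default phantom-trained detector (trained once per session and
    shared with the pipeline's own cache)."""
    from rvlvcad.pipeline import PipelineConfig, get_detector

    return get_detector(PipelineConfig())


@pytest.fixture(scope="session")
def default_phantom():
    """The default phantom and its analytic truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def quiet_phantom():
    """A noiseless phantom without atria (the simplest stated geometry)."""
    spec = PhantomSpec(noise_sigma=0.0, atrium_scale=0.0, rng_seed=1)
    return generate_phantom(spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
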