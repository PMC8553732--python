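import numpy as np
import pytest

from telofish import GeneratorParams, generate_scene, render_scene


def small_params(**overrides) -> GeneratorParams:
    """Compact scene (96x96x20 voxels) keeping unit tests fast."""
    base = dict(
        n_spots_per_nucleus=20,
        nucleus_semi_axes_nm=(1500.0, 3000.0, 3000.0),
        shape_zyx=(20, 96, 96),
        poisson_noise=False,
    )
    base.update(overrides)
    return GeneratorParams(**base)


@pytest.fixture(scope="session")
def small_scene():
    """Noiseless compact scene with its rendered channel pair."""
    truth = generate_scene(small_params(), seed=7)
    dapi, telo = render_scene(truth, quantize=False)
    return truth, dapi, telo


@pytest.fixture(scope="session")
def noisy_scene():
    """Compact scene with Poisson noise, as the pipeline normally sees."""
    truth = generate_scene(small_params(poisson_noise=True), seed=11)
    dapi, telo = render_scene(truth)
    return truth, dapi, telo


@pytest.fixture
def rng():
    return np.random.default_rng(123)
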