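import numpy as np
import pytest

from mitoscore import SyntheticSpec, analyze_image, generate


@pytest.fixture(scope="session")
def scene25():
    """Default synthetic field: 25 separated nuclei, 40 granules."""
    spec = SyntheticSpec(seed=1)
    image, truth = generate(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def scene25_analysis(scene25):
    _, image, _ = scene25
    return analyze_image(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240403)
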