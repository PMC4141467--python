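import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from edgeint.contrast import extract_edges
from edgeint.integration import ModelConfig
from edgeint.selection import SpotlightSpec, apply_gain_field
from edgeint.stimuli import make_disk_annulus, make_staircase_gelb

GELB_REFLECTANCES = [0.03, 0.09, 0.27, 0.81, 0.9]


@pytest.fixture(scope="session")
def decremental_disk():
    """Fig-5-style display: disk 30 < annulus 90 > background 10."""
    return make_disk_annulus(30.0, 90.0, 10.0)


@pytest.fixture(scope="session")
def decremental_edges(decremental_disk):
    image, regions = decremental_disk
    edges = extract_edges(image, regions)
    return apply_gain_field(edges, SpotlightSpec())


@pytest.fixture(scope="session")
def gelb_plain():
    return make_staircase_gelb(GELB_REFLECTANCES)


@pytest.fixture(scope="session")
def gelb_insulated():
    return make_staircase_gelb(
        GELB_REFLECTANCES, frame={"reflectance": 0.9, "thickness": 1.0}
    )


@pytest.fixture
def default_config():
    return ModelConfig()


@pytest.fixture
def ideal_config():
    return ModelConfig(ideal_observer=True)
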