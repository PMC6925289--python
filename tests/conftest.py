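import pytest
from hypothesis import HealthCheck, settings

import arraydpcr as a

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_geometry():
    """A 20 x 25 = 500-well array: same well physics, fast to render."""
    return a.ArrayGeometry(rows=20, cols=25)


@pytest.fixture(scope="session")
def small_config(small_geometry):
    return a.SimulationConfig(seed=11, geometry=small_geometry)


@pytest.fixture(scope="session")
def small_run(small_config):
    """(truth, images, ntc_images) for the default small config."""
    truth = a.simulate_occupancy(small_config)
    images = a.render_array_images(truth, small_config)
    ntc_images, ntc_truth = a.make_ntc_imageset(small_config)
    return truth, images, ntc_images, ntc_truth


@pytest.fixture(scope="session")
def small_analysis(small_run):
    _, images, ntc_images, _ = small_run
    return a.analyze_run(images, ntc_images, min_ntc_valid=100)
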