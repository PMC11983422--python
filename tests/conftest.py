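import numpy as np
import pytest

from stemleaf3d.synthetic import LeafSpec, PlantSpec, generate_plant, make_toy_dataset


@pytest.fixture(scope="session")
def quarter_circle_plant():
    """Vertical stem of length 10 with one quarter-circle leaf of radius 10."""
    leaf = LeafSpec(
        attach_height_frac=0.5,
        azimuth_deg=0.0,
        kind="arc",
        radius=10.0,
        sweep_deg=90.0,
        droop_deg=45.0,
        max_width=1.2,
    )
    spec = PlantSpec(
        stem_radius=0.1,
        stem_length=10.0,
        stem_tilt_deg=0.0,
        leaves=(leaf,),
        points_per_organ=1024,
        noise_sd=0.0,
        seed=42,
    )
    return generate_plant(spec)


@pytest.fixture(scope="session")
def toy_dataset_small():
    return make_toy_dataset(6, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
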