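import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from splinesound.features import FeaturizeConfig
from splinesound.interpolation import GridUpsampleConfig
from splinesound.synthetic import default_class_specs, generate_dataset
from splinesound.timefreq import CWTConfig, MelConfig, STFTConfig

DESK_RATE = 4000
DESK_DURATION = 2.0


@pytest.fixture(scope="session")
def desk_features() -> FeaturizeConfig:
    """Small single-CPU feature configuration used across tests."""
    return FeaturizeConfig(
        stft=STFTConfig(),
        mel=MelConfig(),
        cwt=CWTConfig(window_len=256, n_scales=32, scale_max=256),
        upsample=GridUpsampleConfig(),
        image_size=32,
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A 4-class separable synthetic dataset: 10 records/class, 2 s @ 4 kHz."""
    out = tmp_path_factory.mktemp("dataset")
    specs = default_class_specs(DESK_RATE, snr_db=10.0, n_classes=4)
    manifest = generate_dataset(specs, 10, DESK_DURATION, DESK_RATE, out, seed=0)
    return out, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
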