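import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_synthetic_results():
    """One fitted small synthetic range shared by model/pipeline tests."""
    from oroshift import MountainRangeModel, SyntheticRangeConfig

    cfg = SyntheticRangeConfig(
        target_class="pyramid",
        grid_shape=(32, 32),
        amplitude=2000.0,
        seed=11,
        range_id="shared-pyramid",
    )
    model = MountainRangeModel.from_synthetic(cfg)
    return model.fit(n_boot=299, seed=5)
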