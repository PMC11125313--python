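import numpy as np
import pytest
from hypothesis import settings

from mipsense import colorimetry, synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_response():
    return synthetic.PlateResponseModel(seed=1)


@pytest.fixture(scope="session")
def calibration_table(default_response):
    """Feature table of the frozen synthetic calibration series:
    0-20 mg/L in 1 mg/L steps, two replicates, two 16x16 ROIs per plate."""
    series = synthetic.generate_calibration_series(
        [float(c) for c in range(21)], default_response, replicates=2
    )
    rois = [colorimetry.ROISpec(8, 8), colorimetry.ROISpec(40, 40)]
    return colorimetry.build_feature_table([(img, c, rois) for img, c in series])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
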