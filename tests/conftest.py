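import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capiscore.model import ImageMeasurement, NvcExam

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_exam(exam_id="E1", calibrated=True, images=None, n_images=10, **image_kwargs):
    """Small hand-rolled exam for unit tests."""
    if images is None:
        defaults = dict(
            n_capillaries=15, width_mm=1.5, n_giant=0, n_abnormal=0,
            n_tortuous=0, n_haemorrhages=0,
        )
        defaults.update(image_kwargs)
        images = [
            ImageMeasurement(image_id=f"{exam_id}_I{i}", **defaults)
            for i in range(n_images)
        ]
    return NvcExam(exam_id, calibrated, tuple(images))


@pytest.fixture
def simple_exam():
    return make_exam()
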