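import numpy as np
import pytest

from femurmetrics.synthetic import FemurParameters, generate_specimen


def make_params(rng=None, noise_sd_mm=0.0, **overrides):
    """A valid random (or mean-valued) parameter set."""
    if rng is None:
        values = dict(
            nsa_deg=126.3,
            anteversion_deg=18.8,
            fnsao_mm=6.1,
            gt_to_slsni_mm=40.3,
            neck_axis_length_mm=94.1,
            bow_radius_mm=1200.0,
        )
    else:
        values = dict(
            nsa_deg=rng.uniform(105.0, 150.0),
            anteversion_deg=rng.uniform(-10.0, 40.0),
            fnsao_mm=rng.uniform(0.5, 15.0),
            gt_to_slsni_mm=rng.uniform(25.0, 55.0),
            neck_axis_length_mm=rng.uniform(80.0, 115.0),
            bow_radius_mm=rng.uniform(700.0, 2500.0),
        )
    values.update(noise_sd_mm=noise_sd_mm)
    values.update(overrides)
    return FemurParameters(**values)


@pytest.fixture
def mean_params():
    return make_params()


@pytest.fixture
def clean_generated(mean_params):
    return generate_specimen(mean_params)


@pytest.fixture
def clean_specimen(clean_generated):
    return clean_generated.specimen


@pytest.fixture
def rng():
    return np.random.default_rng(20220304)
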