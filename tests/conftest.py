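import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mvbocc.modelspec import ModelSpec
from mvbocc.simulate import SyntheticTruth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20140615)


@pytest.fixture
def toy_spec():
    """Two-species intercept-only model with a pairwise occurrence term."""
    return ModelSpec(
        species=("a", "b"),
        occurrence={"a": ("const",), "b": ("const",)},
        detection={"a": ("const",), "b": ("const",)},
        pairs={("a", "b"): ("const",)},
        name="toy",
    )


@pytest.fixture
def toy_truth(toy_spec):
    return SyntheticTruth(
        spec=toy_spec,
        params={
            "psi[a]:const": 0.0,
            "psi[b]:const": 0.0,
            "psi[a~b]:const": -0.5,
            "p[a]:const": -0.5,
            "p[b]:const": -0.5,
        },
    )


@pytest.fixture
def small_events():
    """Hand-written events on three deployed sites."""
    rows = [
        ("s1", "grizzly", "2014-06-16 08:00"),
        ("s1", "grizzly", "2014-06-16 08:01"),
        ("s1", "black", "2014-07-01 22:30"),
        ("s2", "motorised", "2014-06-20 14:00"),
        ("s2", "grizzly", "2014-08-01 06:00"),
        ("s3", "non-motorised", "2014-07-15 12:00"),
    ]
    return pd.DataFrame(rows, columns=["site_id", "category", "timestamp"])


@pytest.fixture
def small_deployments():
    return pd.DataFrame(
        {
            "site_id": ["s1", "s2", "s3"],
            "start": ["2014-06-15", "2014-06-15", "2014-07-01"],
            "end": ["2014-08-25", "2014-08-25", "2014-08-25"],
            "lndroad": [6.1, 7.0, 5.5],
            "lndstream": [5.0, 5.8, 6.2],
            "elevation": [1200.0, 1750.0, 1400.0],
            "ndvi": [0.7, 0.8, 0.6],
            "protected": [1, 0, 1],
        }
    )
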