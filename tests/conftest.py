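import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One small end-to-end synthetic study shared across tests."""
    from xylomir.study import run_synthetic_study

    outdir = tmp_path_factory.mktemp("small_study")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, study, metrics = run_synthetic_study(
            seed=11, outdir=outdir, depth=20_000, degradome_depth=5_000)
    return result, study, metrics
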