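import numpy as np
import pytest
import yaml
from hypothesis import HealthCheck, settings

import tobacco_ecea as te

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return te.load_default_config()


@pytest.fixture(scope="session")
def population(bundle):
    return te.build_population(bundle)


@pytest.fixture(scope="session")
def raw_config():
    with open(te.default_config_path()) as fh:
        return yaml.safe_load(fh)


@pytest.fixture
def write_config(tmp_path):
    """Write a (possibly mutated) config dict to a temp file and return its path."""

    def _write(cfg):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg))
        return path

    return _write


@pytest.fixture(scope="session")
def income_model(bundle):
    return te.income_model_from_params(bundle.income)


def total_deaths(bundle, policy, **kw):
    return te.run_policy(bundle, policy, **kw).total("deaths_averted")
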