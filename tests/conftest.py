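import dataclasses as dc

import pytest

import fopfl_caries as fc


@pytest.fixture(scope="session")
def default_cfg():
    return fc.default_config()


@pytest.fixture(scope="session")
def small_cfg(default_cfg):
    """Default parameters with a small simulated cohort for fast tests."""
    return dc.replace(default_cfg,
                      controls=dc.replace(default_cfg.controls, n_individuals=5_000))


@pytest.fixture()
def config_dict(default_cfg):
    from fopfl_caries.params import config_to_dict

    return config_to_dict(default_cfg)
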