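import pytest

from surveyscreen import RuleConfig, default_geo_table


@pytest.fixture
def config():
    return RuleConfig()


@pytest.fixture
def geo():
    return default_geo_table()
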