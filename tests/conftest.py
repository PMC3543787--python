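import pytest

from acs_cea.parameters import builtin_parameter_set


@pytest.fixture(params=[34, 35, 36], ids=lambda w: f"ga{w}")
def builtin_each_week(request):
    return builtin_parameter_set(request.param)


@pytest.fixture
def builtin34():
    return builtin_parameter_set(34)
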