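import pytest

from retequil import load_parameters


@pytest.fixture()
def default_params():
    return load_parameters()
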