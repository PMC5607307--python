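import pytest

from meshcohort.codesets import load_codesets


@pytest.fixture(scope="session")
def registry():
    return load_codesets()
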