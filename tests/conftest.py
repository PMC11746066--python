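import pytest

import tkicea as t


@pytest.fixture(scope="session")
def basecase():
    """Packaged base case; session-scoped and shared — clone before mutating."""
    return t.builtin_basecase()


@pytest.fixture(scope="session")
def basecase_results(basecase):
    return t.run_all(basecase)
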