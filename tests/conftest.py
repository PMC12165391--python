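import warnings

import pytest


@pytest.fixture(autouse=True)
def _quiet_solver_warnings():
    """Rounding/clipping diagnostics are expected in stochastic handoffs."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="non-integer initial amounts rounded")
        warnings.filterwarnings(
            "ignore", message="deterministic solution went negative")
        yield
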