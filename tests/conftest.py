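import pytest

from lincskit.spec_model import load_builtin_specs


@pytest.fixture(scope="session")
def specs():
    """The built-in specification registry (load once per session)."""
    return load_builtin_specs()


@pytest.fixture()
def ledger():
    from lincskit.registry import RegistryLedger
    return RegistryLedger()
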