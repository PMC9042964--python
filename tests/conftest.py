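import pytest

from osteocea import MarkovCohortModel, make_reference_fixture


@pytest.fixture(scope="session")
def reference_config():
    return make_reference_fixture()


@pytest.fixture(scope="session")
def reference_model(reference_config):
    return MarkovCohortModel(reference_config)


@pytest.fixture(scope="session")
def reference_run(reference_model):
    """Deterministic traces, ledgers and accruals for every regimen."""
    return {
        name: reference_model.run_regimen(name)
        for name in reference_model.regimen_names
    }
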