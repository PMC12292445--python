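"""Shared fixtures: the drug model and the expensive study simulations are
built once per session and reused across test modules."""

import pytest

from baripbpk import (
    DispositionParams,
    StudyConfig,
    default_physiology,
    run_study,
    vardenafil_fixture,
)


@pytest.fixture(scope="session")
def drug():
    """Vardenafil with its pH-solubility model fitted."""
    return vardenafil_fixture().fitted()


@pytest.fixture(scope="session")
def disposition(drug):
    return DispositionParams.from_drug(drug)


@pytest.fixture(scope="session")
def healthy_tract():
    return default_physiology()


@pytest.fixture(scope="session")
def study(drug):
    """The full pre/post-surgery study at 10 + 20 mg (one run, reused)."""
    return run_study(StudyConfig(drug=drug))
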