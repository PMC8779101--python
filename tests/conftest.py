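import importlib.resources

import pytest

from poflux import (
    apply_po_ratio,
    build_core_fixture,
    fixture_role_map,
    read_model,
)


def ijo1366_sbml_path() -> str:
    """The iJO1366 SBML file shipped inside the installed cobra distribution."""
    return str(importlib.resources.files("cobra.data") / "iJO1366.xml.gz")


@pytest.fixture()
def core_template():
    return build_core_fixture()


@pytest.fixture()
def core_roles():
    return fixture_role_map()


@pytest.fixture()
def core_at(core_template, core_roles):
    """Parameterize the core network at a given P/O ratio."""

    def _apply(po):
        return apply_po_ratio(core_template, po, core_roles)

    return _apply


@pytest.fixture(scope="session")
def ijo1366():
    """The genome-scale E. coli model, parsed by the package's own reader."""
    return read_model(ijo1366_sbml_path())
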