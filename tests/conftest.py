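import pytest

from mechcycle.cli_io import fixtures


@pytest.fixture(scope="session")
def table4_sets():
    """The four packaged docking-constant sets, in fixture row order."""
    return fixtures.load_binding_sets()


@pytest.fixture(scope="session")
def table1_values():
    """The six packaged replicate IC50 values (mg/mL)."""
    return fixtures.load_ic50_replicates()


@pytest.fixture(scope="session")
def betulin_row(table4_sets):
    return next(s for s in table4_sets if s.ligand_id == "Betulin")
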