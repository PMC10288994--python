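import pytest

from fusemble import fixtures
from fusemble.annotation import read_gtf
from fusemble.filters import FilterConfig
from fusemble.harmonize import AliasTable


@pytest.fixture(scope="session")
def annotation():
    """The deterministic toy annotation (no file round-trip)."""
    return fixtures.generate_annotation()


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig.default()


@pytest.fixture(scope="session")
def aliases():
    return AliasTable.bundled()


@pytest.fixture(scope="session")
def cell_cohort(tmp_path_factory):
    """The cell-line scenario materialized once per session."""
    out = tmp_path_factory.mktemp("cells")
    spec = fixtures.scenario_cell_lines(seed=1)
    paths = fixtures.generate_cohort(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def patient_cohort(tmp_path_factory):
    """The patient scenario materialized once per session."""
    out = tmp_path_factory.mktemp("patients")
    spec = fixtures.scenario_patients(seed=1)
    paths = fixtures.generate_cohort(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def cohort_annotation(cell_cohort):
    """Annotation as read back from the emitted GTF (exercises read_gtf)."""
    _, paths = cell_cohort
    return read_gtf(paths["annotation"])
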