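import pytest

from metabosearch import generate_fixture_mrdb


@pytest.fixture(scope="session")
def fixture_db():
    """The deterministic synthetic organism database used across tests."""
    return generate_fixture_mrdb(seed=1)


@pytest.fixture()
def records_by_name(fixture_db):
    return {rec.name: rec for rec in fixture_db}


EXPORT_HEADER = "name\tformula\taverage_mw\tsmiles\tpathways\tcas_id\n"


@pytest.fixture()
def export_writer(tmp_path):
    """Write a minimal compound/pathway export TSV and return its path."""

    def _write(rows, header=EXPORT_HEADER, fname="export.tsv"):
        path = tmp_path / fname
        path.write_text(header + "".join(r + "\n" for r in rows), encoding="utf-8")
        return path

    return _write
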