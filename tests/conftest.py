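import numpy as np
import pytest

from gjqsar import compound_table


@pytest.fixture(scope="session")
def packaged_dataset():
    return compound_table.load_packaged_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def table_csv(tmp_path):
    """Factory writing a small compound-table CSV and returning its path."""

    def _write(rows, header=None, name="table.csv"):
        header = header or (
            "cid,name,species,assay,neg_log_e_ic50,A,B,exclusion_flags"
        )
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path

    return _write
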