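import numpy as np
import pandas as pd
import pytest

from ache_qsar.descriptors import load_smarts_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_smarts_catalog()


@pytest.fixture(scope="session")
def toy_raw_table(tmp_path_factory):
    """A 5-row generic-dialect activity CSV with one blank value cell."""
    path = tmp_path_factory.mktemp("raw") / "toy.csv"
    pd.DataFrame(
        {
            "compound_id": ["C1", "C2", "C3", "C4", "C5"],
            "smiles": ["CCO", "CCN", "CCC", "CCCl", "CCF"],
            "endpoint": ["IC50", "IC50", "IC50", "Ki", "Ki"],
            "qualifier": ["=", "<", "=", "=", "="],
            "value": ["100", "50", "", "10", "20"],
            "unit": ["nM", "nM", "nM", "nM", "nM"],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)
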