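import numpy as np
import pytest

from scqpcr import CtTable, fak_study_spec, generate, normalize


@pytest.fixture
def tiny_table() -> CtTable:
    """3 cells x 3 genes with one failed reaction; hand-checkable numbers."""
    return CtTable(
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["gA", "gB", "gC"],
        ct=np.array(
            [
                [20.0, 21.0, 30.0],
                [22.0, np.nan, 24.0],
                [24.0, 23.0, 18.0],
            ]
        ),
        group=np.array(["WT", "WT", "KO"], dtype=object),
        chip=np.array(["chip1", "chip1", "chip2"], dtype=object),
    )


@pytest.fixture(scope="session")
def study_data():
    """One realization of the default keratinocyte experiment + truth."""
    table, truth = generate(fak_study_spec(seed=20260922))
    return table, truth


@pytest.fixture(scope="session")
def study_matrix(study_data):
    table, _ = study_data
    return normalize(table)
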