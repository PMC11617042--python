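import numpy as np
import pandas as pd
import pytest

from mucohub.tabio import AbundanceTable, StudyMetadata


@pytest.fixture
def small_table() -> AbundanceTable:
    counts = np.array(
        [
            [25, 10, 5, 40, 12, 30],
            [25, 20, 15, 10, 18, 5],
            [25, 30, 35, 20, 40, 25],
            [25, 40, 45, 30, 30, 40],
        ],
        dtype=float,
    )
    return AbundanceTable(
        ["taxA", "taxB", "taxC", "taxD"],
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        counts,
    )


@pytest.fixture
def small_metadata() -> StudyMetadata:
    ids = ["s1", "s2", "s3", "s4", "s5", "s6"]
    return StudyMetadata(
        ids,
        pd.Series(["Ctrl", "Ctrl", "Ctrl", "HFD", "HFD", "HFD"], index=ids),
        covariates=pd.DataFrame({"body_weight": [24.0, 25.5, 23.8, 26.1, 27.0, 25.2]}, index=ids),
        phenotypes=pd.DataFrame({"FITC": [1.0, 1.2, 0.9, 2.8, 3.1, 2.5]}, index=ids),
    )
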