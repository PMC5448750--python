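import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from connscreen.io_tables import DEFAULT_AGES, ExpressionTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> ExpressionTable:
    """3 genes x 7 ages with one missing cell (gene b at E15.5)."""
    data = pd.DataFrame(
        [
            [0.1, 0.2, 0.3, 0.4, 0.3, 0.2, 0.1],
            [0.2, 0.1, np.nan, 0.5, 0.6, 0.2, 0.2],
            [0.0, 0.0, 0.1, 0.2, 0.4, 0.8, 0.9],
        ],
        index=["a", "b", "c"],
        columns=list(DEFAULT_AGES),
    )
    data.index.name = "gene_id"
    return ExpressionTable(data)


@pytest.fixture
def toy_annotations() -> pd.DataFrame:
    """10 genes: 5 in clusters {0, 2}, of which 3 extracellular, 1 uniform."""
    return pd.DataFrame(
        {
            "cluster": [0, 0, 2, 2, 2, 1, 1, 3, 3, 3],
            "localisation": [
                "secreted", "nuclear", "gpi_or_single_pass", "multi_pass",
                "cytoplasmic", "secreted", "nuclear", "multi_pass",
                "cytoplasmic", "nuclear",
            ],
            "group": [1, 5, 2, 4, 5, 1, 5, 3, 6, 5],
            "differential_flag": [
                "uniform", "unknown", "selective", "differential", "unknown",
                "unknown", "unknown", "unknown", "unknown", "unknown",
            ],
        },
        index=[f"g{i}" for i in range(10)],
    )
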