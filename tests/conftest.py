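import pandas as pd
import pytest

from aenet.synthetic import generate_cohort, planted_cluster_config


@pytest.fixture
def tiny_events() -> pd.DataFrame:
    """Two patients: P1 has AEs a and b, P2 has AE a; plus one drug record."""
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P1"],
            "term": ["a", "b", "a", "drugX"],
            "term_type": ["AE", "AE", "AE", "drug"],
            "count": [2, 1, 3, 1],
        }
    )


@pytest.fixture(scope="session")
def planted_cohort() -> pd.DataFrame:
    """Session-cached cohort with three planted clusters (seed 0)."""
    return generate_cohort(planted_cluster_config(seed=0))
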