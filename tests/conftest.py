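import logging

import numpy as np
import pandas as pd
import pytest

from eduscore.concordance import SOCIETIES
from eduscore.synthetic import CohortConfig


@pytest.fixture(autouse=True)
def _quiet_smog():
    # short synthetic documents trip the SMOG small-sample warning by design
    logger = logging.getLogger("eduscore.text_metrics")
    level = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(level)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return CohortConfig(n_profiles=6, seed=42)


@pytest.fixture
def demo_table():
    """Tiny hand-built guideline table with known weighted scores:
    T1 -> +2.0 (SR x5), T2 -> +1.5 (SR x3), T3 -> -0.5 (CRA x2),
    T4 -> 0.0 (INC x3)."""
    rows = [
        {"treatment_id": "T1", "name": "exercise",
         "ACR": "SR", "OARSI": "SR", "ESCEO": "SR", "AAOS": "SR", "NICE": "SR"},
        {"treatment_id": "T2", "name": "acetaminophen",
         "ACR": "SR", "OARSI": "SR", "ESCEO": "SR", "AAOS": "NA", "NICE": "NA"},
        {"treatment_id": "T3", "name": "opioids",
         "ACR": "CRA", "OARSI": "CRA", "ESCEO": "NA", "AAOS": "NA", "NICE": "NA"},
        {"treatment_id": "T4", "name": "massage",
         "ACR": "INC", "OARSI": "INC", "ESCEO": "INC", "AAOS": "NA", "NICE": "NA"},
    ]
    return pd.DataFrame(rows, columns=["treatment_id", "name", *SOCIETIES])
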