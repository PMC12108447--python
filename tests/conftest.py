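import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from betalactam_tdm.cohort import CohortConfig, generate_cohort, to_frame
from betalactam_tdm.pk import DRUG_PROFILES


@pytest.fixture(scope="session")
def cefepime():
    return DRUG_PROFILES["cefepime"]


@pytest.fixture(scope="session")
def small_cohort():
    """A study-sized default cohort (297 episodes), seed-fixed."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def small_cohort_df(small_cohort):
    return to_frame(small_cohort)
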