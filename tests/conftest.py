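import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from activemon.synthetic import CohortSpec, generate_cohort
from activemon.types import Cohort, Study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def manifest_cohort():
    spec = CohortSpec(
        study=Study.OLE,
        cohort=Cohort.MANIFEST,
        n_participants=40,
        severity_mean=0.5,
        severity_sd=0.2,
        seed=77,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def one_participant(manifest_cohort):
    return manifest_cohort[0]
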