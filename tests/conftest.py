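import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from mdfnet import (
    CohortSpec, PreprocessConfig, generate_cohort, preprocess_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort at reduced duration/rate, strong class contrast."""
    spec = CohortSpec(n_hc=6, n_pd=6, duration_s=20.0, base_rate=125.0,
                      effect_size=4.0, rng_seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    """Default-pipeline segments (1 s at 20 Hz) for the small cohort."""
    segments, report = preprocess_cohort(small_cohort, PreprocessConfig(), rng_seed=0)
    return segments


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
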