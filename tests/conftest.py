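import numpy as np
import pandas as pd
import pytest

from eegdx.core import concat_epochsets
from eegdx.pipeline import extract_features
from eegdx.preprocess import PreprocessConfig, preprocess_recording
from eegdx.synthetic import default_specs, generate_cohort, generate_recording

#: Master seed for the shared synthetic cohort used in acceptance-level
#: tests; fixed so the suite is reproducible run to run.
COHORT_SEED = 123


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    """Feature table of the default cohort (10 CN + 10 AD, 2 min each).

    Built once per session: generate -> preprocess -> extract the 18
    features per epoch.  Several acceptance-level tests share it.
    """
    cn, ad = default_specs()
    recordings = generate_cohort(cn, ad, seed=COHORT_SEED)
    sets = [preprocess_recording(rec, PreprocessConfig())[0]
            for rec in recordings]
    return extract_features(concat_epochsets(sets), seed=COHORT_SEED)


@pytest.fixture()
def short_recording():
    """One 12-s CN-like recording for fast unit tests."""
    cn, _ = default_specs()
    return generate_recording(cn.copy_with(duration_s=12.0), "CN01", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
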