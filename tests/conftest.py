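import warnings

import numpy as np
import pandas as pd
import pytest

from rhythmage import synth
from rhythmage.features import EpochSeries


@pytest.fixture(scope="session")
def clean_cosine_series():
    """Noise-free 7-day cosinor series: M=50, A=20, peak at 14:00."""
    params = synth.SubjectParams("clean", mesor=50.0, amplitude=20.0,
                                 acrophase_h=14.0)
    return synth.simulate_activity_series(params, days=7, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Truth-level cohort (no minute traces) for table-stage tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.generate_cohort(synth.default_config(400, seed=7),
                                     with_traces=False)


@pytest.fixture(scope="session")
def traced_cohort():
    """Small cohort with minute traces for feature-extraction tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.generate_cohort(synth.default_config(60, seed=11))


def make_series(enmo, epoch_s=60, wear=None):
    enmo = np.asarray(enmo, dtype=float)
    if wear is None:
        wear = np.ones(enmo.size, dtype=bool)
    return EpochSeries("t", pd.Timestamp("2015-01-05"), epoch_s, enmo, wear)
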