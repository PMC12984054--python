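import logging
import warnings

import numpy as np
import pytest

from stas_habitat.ct_preprocess import apply_window
from stas_habitat.synthetic_cohort import PhantomConfig, generate_cohort

logging.getLogger("stas_habitat").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight default-condition phantom patients, shared across test modules."""
    return generate_cohort(PhantomConfig(n_patients=8, seed=7))


@pytest.fixture(scope="session")
def windowed_patient(small_cohort):
    """First phantom patient with a lung-window-normalized CT."""
    p = small_cohort[0]
    return p, apply_window(p.ct)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
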