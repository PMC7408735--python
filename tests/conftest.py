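import numpy as np
import pytest

from sojourn import FeatureClass, NaturalHistoryParams


@pytest.fixture(scope="session")
def period2_params():
    """Parameter set at the published 1996-2010 point estimates."""
    mk = NaturalHistoryParams.from_mst
    return {
        FeatureClass.STELLATE: mk(78e-5, 3.76, 0.95, "1996-2010"),
        FeatureClass.CIRCULAR: mk(66e-5, 2.65, 0.95, "1996-2010"),
        FeatureClass.POWDERY_CRUSHED_STONE: mk(46e-5, 4.26, 0.95, "1996-2010"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def typical_params():
    """A single realistic triple used across likelihood tests."""
    return NaturalHistoryParams(lambda1=0.002, lambda2=0.266, sensitivity=0.8)
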