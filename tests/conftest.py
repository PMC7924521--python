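import numpy as np
import pytest

import intervalscore as ics


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def step_fixture():
    """Small seeded dataset from a single step-function variable plus one
    noise variable; used for sparsification checks."""
    truth = ics.GenerativeTruth(
        variables=[
            ics.TrueVariable(thresholds=(0.5,), contributions=(-2.0, 2.0)),
            ics.TrueVariable(contributions=(0.0,)),
        ],
        seed=11,
    )
    X, y, _ = ics.make_piecewise_dataset(truth, 200)
    return X, y, truth


@pytest.fixture
def small_expansion(step_fixture):
    """Binning + both encodings + difference structure for the step data."""
    X, y, _ = step_fixture
    scheme = ics.build_scheme(X, ["continuous", "continuous"], [(0,), (1,)], 6)
    Z_lp = ics.lp_encode(X, scheme)
    Z_en = ics.en_encode(X, scheme)
    diff_lp = ics.build_difference_structure(scheme, "lp")
    diff_en = ics.build_difference_structure(scheme, "en")
    return X, y, scheme, Z_lp, Z_en, diff_lp, diff_en
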