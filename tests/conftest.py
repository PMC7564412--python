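import numpy as np
import pytest

from atdosim.survival import SurvivalRecord
from atdosim.synthetic import default_biodist_truth, gen_biodistribution


@pytest.fixture(scope="session")
def biodist_truth():
    return default_biodist_truth()


@pytest.fixture(scope="session")
def noisy_table(biodist_truth):
    """One paper-design synthetic biodistribution table (CV 15%, n=3)."""
    return gen_biodistribution(biodist_truth, seed=11)


@pytest.fixture(scope="session")
def noiseless_table(biodist_truth):
    from atdosim.synthetic import BiodistTruth

    truth0 = BiodistTruth(organs=biodist_truth.organs, noise_cv=0.0)
    return gen_biodistribution(truth0, seed=0)


def make_records(pairs, group="g", prefix="a"):
    """Build SurvivalRecords from (time, event) pairs."""
    return [
        SurvivalRecord(f"{prefix}{i}", group, float(t), bool(e))
        for i, (t, e) in enumerate(pairs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
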