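import numpy as np
import pytest
from hypothesis import settings

from kappalen import LengthSample

settings.register_profile("det", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("det")


def integer_sample(model, n, seed, species="syn", chromosome="chr01"):
    """Integerized draws from a model, as the generator would produce them."""
    x = np.maximum(np.ceil(model.sample(n, seed=seed)), 1).astype(np.int64)
    return LengthSample(species=species, chromosome=chromosome, lengths=x)


@pytest.fixture
def make_sample():
    return integer_sample
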