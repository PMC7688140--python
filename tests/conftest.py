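import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_spec():
    from histotranscript import zoo
    return zoo.build_architecture("tiny", 4)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return tiny_spec.materialize(seed=0)


@pytest.fixture(scope="session")
def mini_dataset():
    """A small paired dataset: 3 classes x 10 slides, one tile per slide."""
    from histotranscript import synthetic
    return synthetic.generate_dataset(n_classes=3, slides_per_class=10,
                                      image_size=512, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
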