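import numpy as np
import pytest

import pbspike as pb


@pytest.fixture
def config():
    return pb.AnalysisConfig()


@pytest.fixture
def short_protocol():
    """Light 3-trial protocol used where trial count is irrelevant."""
    return pb.StimulusProtocol(n_repeats=3)


def make_session(seed=0, n=3, **spec_kw):
    spec = pb.PopulationSpec(n_neurons=n, **spec_kw)
    return pb.simulate_population(spec, pb.StimulusProtocol(), seed=seed)


@pytest.fixture
def small_session():
    return make_session(seed=7, n=3, ad_incidence=0.5, silent_fraction=0.2)
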