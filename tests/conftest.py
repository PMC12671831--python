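import warnings

import numpy as np
import pytest

# sklearn's HDBSCAN emits a FutureWarning about its `copy` default; it is
# irrelevant to the contracts under test
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def templates3():
    from umapsort.synth import generate_templates

    return generate_templates(3, 64, seed=7)


@pytest.fixture
def small_recording():
    """Three-unit, 10 s noiseless recording with ground truth."""
    from umapsort.synth import SynthSpec, render_recording

    spec = SynthSpec(n_units=3, rate_hz=20.0, duration_s=10.0, eta=0.0, seed=3)
    return render_recording(spec)
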