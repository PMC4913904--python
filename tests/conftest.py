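import numpy as np
import pytest

from toothseg import phantom, pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """The default noisy 128^3 phantom with bracket, plus exact truth."""
    return phantom.generate()


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    """Full-framework output on the default phantom (shared: ~10 s)."""
    vol, _ = default_phantom
    return pipeline.run_pipeline(vol)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bracket-free phantom (easy-mode pipeline input)."""
    return phantom.generate(phantom.PhantomSpec(noise_sd=0.0, bracket=False))


@pytest.fixture
def sphere_mask():
    """Radius-16 ball in a 48^3 grid (analytic geometry oracle)."""
    zz, yy, xx = np.mgrid[:48, :48, :48]
    return ((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2) < 16 ** 2
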