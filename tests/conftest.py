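import pytest

from iccs import SyntheticSpec, generate_image


@pytest.fixture
def noiseless_spec():
    """Default emitter field with background and noise switched off."""
    return SyntheticSpec(background_a=0.0, background_b=0.0, noise_sigma=0.0)


@pytest.fixture
def default_image():
    return generate_image(SyntheticSpec(phi=0.5, seed=42))
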