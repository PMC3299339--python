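import pytest

from orbct import PhantomSpec, generate_phantom, load_study_table


@pytest.fixture(scope="session")
def records():
    return load_study_table()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, pore-free, undistorted default scene (18 mm implant)."""
    spec = PhantomSpec(noise_sd_hu=0.0, pore_fraction=0.0, seed=7)
    return generate_phantom(spec)
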