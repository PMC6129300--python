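import numpy as np
import pytest

from histobench.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """8-section rigid-perturbed phantom shared by read-only tests."""
    spec = PhantomSpec(
        n_sections=8,
        image_size=(192, 192),
        tissue_radii=(70.0, 55.0),
        curvature_amplitude=5.0,
        max_translation=6.0,
        max_rotation=4.0,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def still_phantom():
    """Unperturbed, gently curved phantom: the stack is already aligned."""
    spec = PhantomSpec(
        n_sections=10,
        image_size=(192, 192),
        tissue_radii=(70.0, 55.0),
        curvature_amplitude=1.5,
        radius_variation=0.005,
        perturbation="none",
        seed=9,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
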