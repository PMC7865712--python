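import numpy as np
import pytest

from pavessel import PhantomSpec, generate_tree_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """A default-size vascular tree phantom with its ground truth."""
    return generate_tree_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def bar_spec():
    """Noiseless straight horizontal trunk of width 9 spanning 64×256."""
    return PhantomSpec(
        image_size=(64, 256), n_trunks=1, trunk_width_px=9, branch_levels=0,
        tortuosity=0.0, noise_sigma=0.0, psf_sigma_px=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def bar_phantom(bar_spec):
    return generate_tree_phantom(bar_spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom
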