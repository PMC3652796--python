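import numpy as np
import pytest

from mbobhe import GrayImage, PhantomSpec, make_bimodal, make_phantom


def fixture_images(n: int, base_seed: int = 0) -> list[GrayImage]:
    """Seeded mix of phantoms and bimodal images (all <= 128x128)."""
    images = []
    for i in range(n):
        seed = base_seed + i
        if i % 3 == 0:
            images.append(make_phantom(PhantomSpec(seed=seed, size=(64, 64))))
        elif i % 3 == 1:
            images.append(make_bimodal(64, 64, 30 + i % 60, 180, 0.4, seed))
        else:
            images.append(
                make_phantom(
                    PhantomSpec(seed=seed, size=(128, 128), bones=2, noise_sigma=4.0)
                )
            )
    return images


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomSpec(seed=7, size=(64, 64)))


@pytest.fixture(scope="session")
def small_fixtures():
    return fixture_images(12)


@pytest.fixture(scope="session")
def acceptance_fixtures():
    """The 50 seeded fixtures used by the property-oracle suite."""
    return fixture_images(50)


@pytest.fixture
def constant_image():
    return GrayImage(np.full((5, 5), 40), 256)
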