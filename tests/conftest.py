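import numpy as np
import pytest

from woundqc.synthetic import SceneSpec, render_scene


def scene_spec(seed: int, sigma: float = 0.0, **kw) -> SceneSpec:
    """Seeded scene with randomized sticker pose, as the fixture suites use."""
    rng = np.random.default_rng(seed)
    defaults = dict(
        checker_center=(float(rng.uniform(180, 380)), float(rng.uniform(110, 240))),
        checker_rotation=float(rng.uniform(-20, 20)),
        blur_sigma=sigma,
        seed=seed,
    )
    defaults.update(kw)
    return SceneSpec(**defaults)


# Fixture pose: sticker beside the wound, as the capture protocol places
# it; the generator's random poses may overlap the wound blob instead.
CLEAR_POSE = dict(checker_center=(350.0, 140.0))


@pytest.fixture(scope="session")
def sharp_scene():
    """Unblurred scene with the sticker beside the wound, ~7% of the frame."""
    return render_scene(scene_spec(seed=11, **CLEAR_POSE))


@pytest.fixture(scope="session")
def blurred_scene():
    """Same pose rendered at heavy defocus (sigma=6)."""
    return render_scene(scene_spec(seed=11, sigma=6.0, **CLEAR_POSE))


@pytest.fixture(scope="session")
def checker_free_scene():
    """Wound blob and background only — nothing to detect."""
    return render_scene(scene_spec(seed=11, include_checker=False))
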