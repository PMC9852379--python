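import numpy as np
import pytest

from hydroparc.synthetic_data import (
    PhantomSpec,
    make_erase_mask,
    make_symmetric_phantom,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom48():
    """A lesion-free, noise-free symmetric phantom with its label map."""
    return make_symmetric_phantom(
        PhantomSpec(image_size=48, n_regions=12, seed=3)
    )


@pytest.fixture(scope="session")
def unilateral_mask48():
    return make_erase_mask(
        48, n_shapes=2, coverage_range=(0.05, 0.2), seed=5, side="left"
    )


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A deliberately small trained inpainting model shared by tests that
    only need a working (not a good) model."""
    import warnings

    from hydroparc import inpainting as ip

    imgs, masks = [], []
    for i in range(8):
        img, _ = make_symmetric_phantom(
            PhantomSpec(image_size=32, n_regions=6, seed=i)
        )
        imgs.append(img)
        masks.append(
            make_erase_mask(32, 1, (0.03, 0.12), seed=i, side="left")
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, log = ip.train(
            list(zip(imgs, masks)),
            ip.GeneratorConfig(base_channels=4),
            epochs=2,
            seed=0,
            batch_size=4,
        )
    return model, log
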