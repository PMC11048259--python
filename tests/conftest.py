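import numpy as np
import pytest

from efastnet import phantom
from efastnet.training import ImageDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def desk_params():
    """Desk-scale phantom: 64 px frames, full injury effect."""
    return phantom.PhantomParams(severity=1.0, size=64, base_seed=7)


@pytest.fixture
def effects(desk_params):
    return phantom.sample_subject_effects(desk_params, 0)


def make_dataset(site: str, n_per_class: int, params, effects,
                 seed: int) -> ImageDataset:
    """Render a balanced single-subject dataset for quick training tests."""
    X, y = [], []
    for i in range(n_per_class):
        for li, lab in enumerate(("negative", "positive")):
            r = np.random.default_rng([seed, li, i])
            if phantom.site_mode(site) == "B":
                fr = phantom.render_bmode(site, lab, params, effects, r)
                X.append(fr.pixels)
            else:
                cap = phantom.render_mmode(site, lab, params, effects, r)
                X.append(cap.matrix[:, :params.size])
            y.append(li)
    return ImageDataset(np.stack(X), np.array(y))


@pytest.fixture
def tiny_cohort(desk_params):
    return phantom.generate_cohort(desk_params, 3, {"RUQ": 4, "HTX_B": 4})
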