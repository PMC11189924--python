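"""Shared fixtures: CI-scale synthetic datasets and a trained model.

All data is generated programmatically; the CI scale (64x64 scenes, a few
dozen images, tens of epochs) is the package's documented desk-scale
configuration for exercising the full pipeline on one CPU.
"""

import numpy as np
import pytest

import pointcell as pc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


CI_SYNTH = pc.SynthConfig(
    image_size=64,
    n_cells_range=(2, 6),
    target_overlap_rate=0.3,
    cell_radius_frac=(0.13, 0.2),
    seed=0,
)

CI_MODEL = pc.ModelConfig(
    widths=(8, 16, 32, 64),
    fpn_width=16,
    epochs=40,
    beta_train=196,
    beta_infer=784,
    seed=7,
)


@pytest.fixture(scope="session")
def ci_train_scenes():
    return pc.generate_dataset(CI_SYNTH, 48, seed=101)


@pytest.fixture(scope="session")
def ci_eval_scenes():
    return pc.generate_dataset(CI_SYNTH, 16, seed=505)


@pytest.fixture(scope="session")
def ci_model(ci_train_scenes):
    """The scaled-down end-to-end model shared by accuracy tests."""
    return pc.train(ci_train_scenes, CI_MODEL, log_every=0)


@pytest.fixture()
def small_scene():
    cfg = pc.SynthConfig(
        image_size=64, n_cells_range=(3, 3), target_overlap_rate=0.2,
        cell_radius_frac=(0.15, 0.2), seed=0,
    )
    return pc.generate_scene(cfg, 42)


def random_mask_set(rng, size=24, n_masks=3):
    """Random blob masks for metric-oracle tests (may overlap)."""
    masks = []
    for _ in range(n_masks):
        m = np.zeros((size, size), dtype=bool)
        cy, cx = rng.integers(2, size - 2, size=2)
        r = rng.integers(2, max(size // 3, 3))
        yy, xx = np.mgrid[0:size, 0:size]
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if m.any():
            masks.append(m)
    if not masks:
        masks = [np.ones((size, size), dtype=bool)]
    return pc.InstanceMaskSet(masks)
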