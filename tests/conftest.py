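"""Shared fixtures: small synthetic images rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from isletquant.synthgen import make_group_preset, render_islet_image


def small_preset(group: str = "ND", **overrides):
    defaults = dict(
        image_shape_px=(384, 384),
        n_islets=2,
        cells_per_islet_mean=25.0,
        cells_per_islet_dispersion=3.0,
    )
    defaults.update(overrides)
    return make_group_preset(group, **defaults)


def clean_preset(group: str = "ND", **overrides):
    """Noiseless, background-free, exocrine-free configuration."""
    defaults = dict(
        noise_sd=0.0,
        background_level=0.0,
        include_exocrine=False,
        illumination_gradient_amplitude=0.0,
    )
    defaults.update(overrides)
    return small_preset(group, **defaults)


@pytest.fixture(scope="session")
def nd_image_truth():
    cfg = small_preset("ND")
    return render_islet_image(cfg, seed=3)


@pytest.fixture(scope="session")
def clean_image_truth():
    cfg = clean_preset("ND")
    return render_islet_image(cfg, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
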