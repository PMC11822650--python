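"""Shared fixtures: synthetic fields generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from synspread import (
    LabelMap,
    MultiChannelImage,
    SyntheticConfig,
    generate_culture,
)
from synspread.experiments import calibrate_culture_thresholds


def make_disc_image(
    centers,
    radii,
    values,
    shape=(200, 200),
    background=100.0,
    channel="NFH",
    pixel_size=1.0,
    extra_channels=None,
):
    """Crisp (unblurred) disc image plus matching label map, for unit tests."""
    img = np.full(shape, background, dtype=np.float64)
    lab = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, ((r, c), rad, v) in enumerate(zip(centers, radii, values), start=1):
        sel = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        img[sel] = v
        lab[sel] = i
    channels = {channel: img}
    if extra_channels:
        channels.update(extra_channels)
    image = MultiChannelImage(channels=channels, pixel_size=pixel_size)
    return image, LabelMap(labels=lab, provenance="MANUAL")


@pytest.fixture(scope="session")
def noiseless_culture():
    cfg = SyntheticConfig(n_cells=60, image_shape=(400, 400), noise_sd=0.0, seed=11)
    image, truth = generate_culture(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def noisy_culture():
    cfg = SyntheticConfig(n_cells=60, image_shape=(400, 400), seed=12)
    image, truth = generate_culture(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def culture_thresholds(noiseless_culture):
    cfg, _, _ = noiseless_culture
    control_cfg = cfg.replace(p_transduce=0.0, p_spread=0.0, seed=21)
    control_img, _ = generate_culture(control_cfg)
    return calibrate_culture_thresholds([control_img])


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    from synspread import generate_fixture_suite

    out = tmp_path_factory.mktemp("suite")
    manifest = generate_fixture_suite(out, seed=0)
    return out, manifest
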