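"""Shared fixtures: small simulated fields and a tiny on-disk dataset."""

from __future__ import annotations

import numpy as np
import pytest

from pics.smear_sim import SmearConfig, make_dataset, render_smear

# small field used throughout the suite: 80 px at 0.55 µm/px holds 1-4 cells
SMALL_CONFIG = SmearConfig(field_size=(80, 80), pixel_size=0.55, rbc_density=12.0)


@pytest.fixture(scope="session")
def small_samples():
    """30 deterministic small smear fields."""
    rng = np.random.default_rng(2024)
    return [
        render_smear(SMALL_CONFIG, np.random.default_rng(rng.integers(2**31)))
        for _ in range(30)
    ]


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 24-image dataset on disk with 4 test images and 2 repeats."""
    out = tmp_path_factory.mktemp("dataset") / "data"
    split = make_dataset(
        out, n_images=24, n_test=4, n_repeats=2, config=SMALL_CONFIG, seed=5
    )
    return out, split
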