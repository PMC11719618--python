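import math

import numpy as np
import pytest

from filametry import ColonySpec, Filament, PipelineConfig


def spoke_spec(
    n_spokes: int,
    radius: float = 100.0,
    length: float = 50.0,
    width: float = 10.0,
    noise_sd: float = 0.0,
    margin: int = 20,
    seed: int = 0,
) -> ColonySpec:
    """Disc plus evenly spaced radial spokes, sized to fit the frame."""
    side = int(2 * (radius + length) + margin)
    filaments = tuple(
        Filament(angle=2 * math.pi * k / n_spokes, length=length, width=width)
        for k in range(n_spokes)
    )
    return ColonySpec(
        image_width=side,
        image_height=side,
        inner_radius=radius,
        filaments=filaments,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def disc_spec():
    return ColonySpec(image_width=300, image_height=300, inner_radius=80, noise_sd=0.0)


@pytest.fixture
def small_config():
    """Pipeline config matched to small synthetic frames (no resampling)."""

    def make(size=(300, 300), **kw):
        kw.setdefault("opening_radius_px", 8.0)
        return PipelineConfig(resolution=size, **kw)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
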