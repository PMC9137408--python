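import numpy as np
import pytest

from ctcdetect import CellSpec, DetectionParams, SyntheticSceneSpec, generate_scene


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def two_cell_scene(noise_sd: float = 0.0) -> SyntheticSceneSpec:
    """One CTC and one leukocyte, well separated, noise optional."""
    ctc = CellSpec(
        center=(130, 130),
        nucleus_radius=25,
        cell_radius=28,
        kind="CTC",
        blue_intensity=200,
        green_intensity=160,
        red_intensity=0,
    )
    leukocyte = CellSpec(
        center=(130, 360),
        nucleus_radius=24,
        cell_radius=36,
        kind="leukocyte",
        blue_intensity=200,
        green_intensity=0,
        red_intensity=150,
    )
    return SyntheticSceneSpec(
        height=260,
        width=500,
        cells=[ctc, leukocyte],
        noise_sd=noise_sd,
        seed=11,
        source_id="two_cell",
    )


@pytest.fixture
def simple_scene():
    """Rendered noise-free two-cell scene with its truth table."""
    return generate_scene(two_cell_scene(noise_sd=0.0))
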