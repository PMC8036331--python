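import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import box

from vinecanopy.synthetic_scene import (
    FieldSpec,
    SceneParams,
    VigourFieldParams,
    assign_truth,
    generate_layout,
    render_scene,
)

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def plot_a_field() -> FieldSpec:
    """22 m x 12 m rectangle with the plot-A planting geometry (2.2 m x 1.2 m)."""
    return FieldSpec(
        boundary=box(0.0, 0.0, 22.0, 12.0),
        row_spacing=2.2,
        vine_spacing=1.2,
        row_azimuth=0.0,
        plot_id="A",
        variety="Chardonnay",
    )


@pytest.fixture
def noiseless_params() -> SceneParams:
    """Rendering with no reflectance noise and no weeds: deterministic spectra."""
    return SceneParams(gsd=0.065, noise_sd=0.0, weed_patch_density=0.0, margin=2.0)


@pytest.fixture
def flat_vigour() -> VigourFieldParams:
    """Degenerate vigour field: every vine gets vigour exactly ``base``."""
    return VigourFieldParams(base=0.5, trend=(0.0, 0.0), n_bumps=0, noise_sd=0.0)


@pytest.fixture
def rendered(plot_a_field, noiseless_params, flat_vigour):
    """A small noiseless scene with its truths, reused by several modules."""
    layout = generate_layout(plot_a_field)
    truths = assign_truth(layout, "BBCH75", flat_vigour, seed=7)
    scene = render_scene(truths, plot_a_field, noiseless_params, seed=7)
    return plot_a_field, truths, scene
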