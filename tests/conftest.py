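"""Shared fixtures: phantoms, models and cached sweeps.

Expensive objects (the full-audio analytic sweeps of the validation
phantom) are session-scoped so the acceptance tests and property tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from uteroacoustics.layered_sphere import LayeredSphereModel, sweep_inner_sphere
from uteroacoustics.media import AIR, get_medium
from uteroacoustics.metrics import twelfth_octave_grid
from uteroacoustics.phantom import icosphere, interior_grid


@pytest.fixture(scope="session")
def audio_band_grid():
    return twelfth_octave_grid(20.0, 20000.0)


@pytest.fixture(scope="session")
def fig_validation_model():
    """Two concentric spheres: air | abdominal-tissue shell | amniotic core."""
    return LayeredSphereModel(
        radii=(0.25, 0.15),
        media=(AIR, get_medium("Abdominal tissue"), get_medium("Amniotic fluid")),
        direction=(1.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def damped_validation_model():
    """Same geometry with the high-attenuation (uterine tissue) core."""
    return LayeredSphereModel(
        radii=(0.25, 0.15),
        media=(AIR, get_medium("Abdominal tissue"), get_medium("Uterine tissue")),
        direction=(1.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def inner_grid_points():
    """Interior evaluation grid of the 0.15 m core with the 0.5 sr exclusion."""
    mesh = icosphere(0.15, 3, region_label="uterus")
    return interior_grid(mesh, spacing=0.30 / 20.0).points


@pytest.fixture(scope="session")
def validation_sweep(fig_validation_model, audio_band_grid, inner_grid_points):
    """Full audio-range analytic sweep of the low-attenuation phantom."""
    return sweep_inner_sphere(
        fig_validation_model, audio_band_grid.frequencies, inner_grid_points
    )


@pytest.fixture(scope="session")
def damped_sweep(damped_validation_model, audio_band_grid, inner_grid_points):
    return sweep_inner_sphere(
        damped_validation_model, audio_band_grid.frequencies, inner_grid_points
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260301)
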