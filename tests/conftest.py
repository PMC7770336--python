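import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pacemap import (
    Landmarks,
    OAPTemplate,
    PacemakerFocus,
    SimulationConfig,
    TissueGeometry,
    render_movie,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> TissueGeometry:
    return TissueGeometry(
        height_px=30,
        width_px=30,
        pixel_pitch_mm=0.1,
        landmarks=Landmarks(ivc_px=(26, 15), svc_px=(4, 15)),
    )


def make_config(
    geometry: TissueGeometry,
    focus_px: tuple[int, int] = (8, 15),
    cl_ms: float = 200.0,
    n_beats: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    polarity: str = "positive",
    first_firing_ms: float = 30.0,
) -> SimulationConfig:
    template = OAPTemplate(upstroke_ms=5.0, apd_ms=60.0)
    duration = first_firing_ms + (n_beats - 1) * cl_ms + template.support_ms + 60.0
    return SimulationConfig(
        geometry=geometry,
        foci=[
            PacemakerFocus(
                position_px=focus_px,
                intrinsic_cl_ms={"baseline": cl_ms},
                first_firing_ms=first_firing_ms,
            )
        ],
        conduction_velocity_mm_per_ms=0.5,
        template=template,
        noise_sd=noise_sd,
        frame_rate_hz=1000.0,
        duration_ms=duration,
        polarity=polarity,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_recording(small_geometry):
    """Noise-free 4-beat single-focus movie with its ground truth."""
    config = make_config(small_geometry)
    movie, truth = render_movie(config)
    return config, movie, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
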