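"""Synthetic voltage-dye movie generator with exact ground truth.

Propagation is modelled as an isotropic constant-velocity (eikonal)
wavefront: the activation time at pixel p for a beat driven by foci with
onsets t_f is ``min_f [ t_f + dist_mm(p, f) / cv ]``. Competing foci
interact by earliest-activation-wins per pixel; foci free-run at their
intrinsic cycle lengths and are not phase-reset by each other's beats.
A firing event landing inside the refractory window of an accepted beat
does not start a beat of its own (but its wavefront joins that beat's
activation field, producing collision patterns).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .types import (
    GroundTruth,
    MovieStack,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

__all__ = ["simulate_activation_field", "render_movie", "simulate_cohort"]


def _distance_grid_mm(config: SimulationConfig, position_px: tuple[int, int]) -> np.ndarray:
    geo = config.geometry
    rows = np.arange(geo.height_px)[:, None]
    cols = np.arange(geo.width_px)[None, :]
    r0, c0 = position_px
    return np.hypot(rows - r0, cols - c0) * geo.pixel_pitch_mm


def simulate_activation_field(
    config: SimulationConfig, beat_onsets: dict[int, float]
) -> np.ndarray:
    """Activation field (ms per pixel) for one beat.

    Parameters
    ----------
    beat_onsets
        Mapping from focus index (into ``config.foci``) to that focus's
        firing time for this beat. Only the listed foci participate.

    Returns
    -------
    (H, W) array of activation times; NaN at masked-out pixels.
    """
    if not beat_onsets:
        raise ValueError("no pacemaker source")
    cv = config.conduction_velocity_mm_per_ms
    field = np.full((config.geometry.height_px, config.geometry.width_px), np.inf)
    for idx, onset in beat_onsets.items():
        focus = config.foci[idx]
        field = np.minimum(field, onset + _distance_grid_mm(config, focus.position_px) / cv)
    field[~config.geometry.mask] = np.nan
    return field


def _firing_trains(config: SimulationConfig) -> dict[int, np.ndarray]:
    """Firing times of every focus over the recording, per its own clock."""
    trains: dict[int, np.ndarray] = {}
    for i, focus in enumerate(config.foci):
        cl = focus.cycle_length(config.condition)
        n = int(np.floor((config.duration_ms - focus.first_firing_ms) / cl)) + 1
        times = focus.first_firing_ms + cl * np.arange(max(n, 0))
        trains[i] = times[(times >= 0) & (times < config.duration_ms)]
    return trains


def _accepted_beats(
    config: SimulationConfig, trains: dict[int, np.ndarray]
) -> list[dict[int, float]]:
    """Group firing events into beats under the refractory rule.

    Each accepted beat is the dict of focus onsets that co-activate it:
    the earliest pending event opens a beat, and every event within the
    refractory window joins it (one event per focus, the earliest).
    """
    events = sorted(
        (t, f) for f, times in trains.items() for t in times
    )
    refractory = config.effective_refractory_ms
    beats: list[dict[int, float]] = []
    i = 0
    while i < len(events):
        onset, focus = events[i]
        beat = {focus: onset}
        j = i + 1
        while j < len(events) and events[j][0] < onset + refractory:
            t, f = events[j]
            beat.setdefault(f, t)
            j += 1
        beats.append(beat)
        i = j
    return beats


def render_movie(config: SimulationConfig) -> tuple[MovieStack, GroundTruth]:
    """Render the optical recording described by ``config``.

    Each pixel's trace is the resting level plus the OAP template
    time-shifted by the pixel's activation time, for every beat; with
    inverted polarity (di-4-ANEPPS convention) the deflection is
    negative-going. I.i.d. Gaussian camera noise with sd
    ``noise_sd * amplitude`` is added per pixel per frame. Deterministic
    for a fixed seed.
    """
    frame_interval_ms = 1000.0 / config.frame_rate_hz
    if config.template.upstroke_ms < 2 * frame_interval_ms:
        raise ValueError(
            f"frame rate {config.frame_rate_hz} Hz too low to resolve a "
            f"{config.template.upstroke_ms} ms upstroke"
        )
    trains = _firing_trains(config)
    if sum(len(t) for t in trains.values()) < 2:
        raise ValueError("duration too short: fewer than 2 firing events")
    beats = _accepted_beats(config, trains)

    geo = config.geometry
    n_frames = int(round(config.duration_ms / frame_interval_ms))
    frames = np.full(
        (n_frames, geo.height_px, geo.width_px),
        config.template.resting_level,
        dtype=float,
    )
    times_ms = np.arange(n_frames) * frame_interval_ms
    sign = -1.0 if config.polarity == "inverted" else 1.0

    fields = np.empty((len(beats), geo.height_px, geo.width_px))
    winning = np.empty(len(beats), dtype=int)
    onsets = np.empty(len(beats))
    for b, beat in enumerate(beats):
        field = simulate_activation_field(config, beat)
        fields[b] = field
        onsets[b] = min(beat.values())
        # winner: focus achieving the minimum activation time at its own pixel
        winning[b] = min(
            beat, key=lambda f: (field[config.foci[f].position_px], f)
        )
        finite = field[geo.mask]
        lo = max(int(np.floor(finite.min() / frame_interval_ms)), 0)
        hi = min(
            int(np.ceil((finite.max() + config.template.support_ms) / frame_interval_ms)) + 1,
            n_frames,
        )
        if hi <= lo:
            continue
        phase = times_ms[lo:hi, None, None] - field[None, :, :]
        contrib = config.template.waveform(np.nan_to_num(phase, nan=-1.0))
        contrib[:, ~geo.mask] = 0.0
        frames[lo:hi] += sign * contrib

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        frames += rng.normal(
            0.0, config.noise_sd * config.template.amplitude, size=frames.shape
        )

    cl = np.full(len(beats), np.nan)
    if len(beats) > 1:
        cl[:-1] = np.diff(onsets)
    truth = GroundTruth(
        beat_times_ms=trains,
        beat_onsets_ms=onsets,
        winning_focus=winning,
        true_activation_field=fields,
        true_cl_ms=cl,
    )
    movie = MovieStack(
        frames=frames.astype(np.float32),
        frame_rate_hz=config.frame_rate_hz,
        pixel_pitch_mm=geo.pixel_pitch_mm,
        polarity=config.polarity,
    )
    return movie, truth


def simulate_cohort(
    configs: list[SimulationConfig],
) -> list[tuple[MovieStack, GroundTruth]]:
    """Render one movie per config; seeds are independent and recorded."""
    if not configs:
        raise ValueError("empty cohort: need at least one config")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) < len(seeds):
        warnings.warn("duplicate seeds across cohort configs", stacklevel=2)
    out = []
    for c in configs:
        logger.info("rendering movie seed=%d condition=%s", c.seed, c.condition)
        out.append(render_movie(c))
    return out
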