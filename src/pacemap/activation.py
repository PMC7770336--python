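"""Beat segmentation, AP50 activation maps, leading-site detection,
heart rate, and sinus-node recovery time.

The activation time of a pixel is the AP50 instant: the moment during the
upstroke at which the normalized optical action potential first crosses
50% of its amplitude, located with linear interpolation between the
bracketing frames (sub-frame resolution).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import ActivationMap, BeatWindow, MovieStack, NormalizedBeat, SnrtResult

logger = logging.getLogger(__name__)

__all__ = [
    "global_trace",
    "segment_beats",
    "activation_time_pixel",
    "activation_map",
    "leading_site",
    "heart_rate",
    "snrt",
]


def global_trace(movie: MovieStack, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Spatially averaged in-mask trace, polarity-corrected (upstroke rising)."""
    h, w = movie.frame_shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    sign = -1.0 if movie.polarity == "inverted" else 1.0
    return sign * movie.frames[:, np.asarray(mask, dtype=bool)].mean(axis=1)


def segment_beats(
    trace: np.ndarray,
    frame_rate_hz: float,
    min_cl_ms: float = 100.0,
) -> list[BeatWindow]:
    """Bracket each depolarization peak of the global trace with a window
    running from the preceding diastolic minimum to the following one.

    Peaks must be separated by at least ``min_cl_ms``. Beats truncated by
    the recording edge (no complete upstroke inside the window) are
    dropped. Returns an empty list (with a warning) when no peaks exist.
    """
    trace = np.asarray(trace, dtype=float)
    dt_ms = 1000.0 / frame_rate_hz
    if len(trace) < 2 * min_cl_ms / dt_ms:
        raise ValueError("trace shorter than two minimal cycle lengths")
    ptp = float(np.ptp(trace))
    if ptp == 0.0:
        logger.warning("constant global trace: no beats found")
        return []
    distance = max(int(round(min_cl_ms / dt_ms)), 1)
    peaks, _ = sps.find_peaks(trace, distance=distance, prominence=0.3 * ptp)
    if len(peaks) == 0:
        logger.warning("no depolarization peaks found")
        return []

    bounds = [int(np.argmin(trace[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(trace[a : b + 1])))
    bounds.append(peaks[-1] + int(np.argmin(trace[peaks[-1] :])))

    windows: list[BeatWindow] = []
    for i, peak in enumerate(peaks):
        start, end = bounds[i], bounds[i + 1]
        if end <= start:
            continue
        seg = trace[start : end + 1]
        amp = seg.max() - seg.min()
        if amp <= 0:
            continue
        # no complete upstroke: the window opens above the AP50 level
        if (trace[start] - seg.min()) / amp > 0.5:
            continue
        windows.append(
            BeatWindow(
                start_frame=int(start),
                end_frame=int(end),
                peak_frame=int(peak),
                t_ref_ms=start * dt_ms,
            )
        )
    return windows


def activation_time_pixel(
    trace: np.ndarray, frame_rate_hz: float
) -> float:
    """AP50 time (ms from the window start) of one normalized beat trace.

    Uses the first upward 0.5-crossing before the window's peak, linearly
    interpolated. Returns NaN when no crossing exists (invalid pixel).
    """
    v = np.asarray(trace, dtype=float)
    if len(v) < 2 or not np.all(np.isfinite(v)):
        return float("nan")
    peak = int(np.argmax(v))
    dt_ms = 1000.0 / frame_rate_hz
    before = v[: peak + 1]
    ups = np.nonzero((before[:-1] < 0.5) & (before[1:] >= 0.5))[0]
    if len(ups) == 0:
        return float("nan")
    i = int(ups[0])
    frac = (0.5 - v[i]) / (v[i + 1] - v[i])
    return (i + frac) * dt_ms


def activation_map(
    beat: NormalizedBeat, frame_rate_hz: float
) -> ActivationMap:
    """Per-pixel AP50 activation map for one normalized beat.

    Vectorized equivalent of applying :func:`activation_time_pixel` to
    every valid pixel; times are relative to the window start.
    """
    data = beat.data
    t, h, w = data.shape
    dt_ms = 1000.0 / frame_rate_hz
    times = np.full((h, w), np.nan)
    valid = beat.valid.copy()

    if t >= 2 and valid.any():
        v = np.nan_to_num(data, nan=-1.0)
        peak = np.argmax(v, axis=0)  # (H, W)
        idx = np.arange(t - 1)[:, None, None]
        crossing = (v[:-1] < 0.5) & (v[1:] >= 0.5) & (idx < peak[None])
        has = crossing.any(axis=0)
        first = np.argmax(crossing, axis=0)
        rr, cc = np.nonzero(has & valid)
        i = first[rr, cc]
        v0 = data[i, rr, cc]
        v1 = data[i + 1, rr, cc]
        times[rr, cc] = (i + (0.5 - v0) / (v1 - v0)) * dt_ms
        valid &= has

    valid &= np.isfinite(times)
    if not valid.any():
        raise ValueError("no activation detected")
    return ActivationMap(times_ms=times, valid=valid)


def _neighbor_offsets(radius: int) -> np.ndarray:
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if (dr, dc) != (0, 0) and dr * dr + dc * dc <= radius * radius
    ]
    return np.asarray(offs)


def leading_site(
    amap: ActivationMap,
    neighbor_radius_px: int = 2,
    neighbor_tolerance_ms: float = 5.0,
) -> tuple[tuple[int, int], float]:
    """Earliest coherent activation site of one beat.

    The earliest valid pixel is accepted only if at least half of its
    valid neighbors within ``neighbor_radius_px`` activate within
    ``neighbor_tolerance_ms`` of it; this rejects salt-and-pepper
    outliers. Rejected candidates are skipped in order of activation
    time. Co-minimal accepted pixels are merged by rounding their
    centroid to the nearest pixel (half-values round away from zero).
    """
    times = amap.times_ms
    valid = amap.valid
    if not valid.any():
        raise ValueError("no valid pixels in activation map")
    h, w = times.shape
    offsets = _neighbor_offsets(int(neighbor_radius_px))

    def coherent(r: int, c: int) -> bool:
        rr = offsets[:, 0] + r
        cc = offsets[:, 1] + c
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[ok], cc[ok]
        nb_valid = valid[rr, cc]
        if not nb_valid.any():
            return True  # isolated-but-only pixel: nothing to contradict it
        close = np.abs(times[rr, cc] - times[r, c]) <= neighbor_tolerance_ms
        return (close & nb_valid).sum() >= 0.5 * nb_valid.sum()

    order = np.argsort(times[valid], kind="stable")
    coords = np.argwhere(valid)[order]
    tvals = times[valid][order]

    i = 0
    n = len(tvals)
    while i < n:
        # group of co-minimal candidates at this time level
        j = i
        while j < n and tvals[j] - tvals[i] <= 1e-9:
            j += 1
        accepted = [
            (int(r), int(c)) for r, c in coords[i:j] if coherent(int(r), int(c))
        ]
        if accepted:
            arr = np.asarray(accepted, dtype=float)
            centroid = arr.mean(axis=0)
            pixel = tuple(int(np.floor(x + 0.5)) for x in centroid)
            # centroid may fall on an invalid pixel; snap to nearest accepted
            if not (valid[pixel] and np.isfinite(times[pixel])):
                k = int(np.argmin(np.abs(arr - centroid).sum(axis=1)))
                pixel = accepted[k]
            return pixel, float(tvals[i])
        i = j
    raise ValueError("no coherent early site")


def heart_rate(windows: Sequence[BeatWindow], frame_rate_hz: float) -> np.ndarray:
    """Per-beat (cl_ms, hr_bpm) from successive peak-to-peak intervals.

    The first beat carries the interval that follows it; every later beat
    carries the interval that precedes it. Returns an (n, 2) array; empty
    for fewer than two beats.
    """
    if len(windows) < 2:
        return np.empty((0, 2))
    dt_ms = 1000.0 / frame_rate_hz
    peaks = np.asarray([w.peak_frame for w in windows], dtype=float) * dt_ms
    gaps = np.diff(peaks)
    cl = np.concatenate([[gaps[0]], gaps])
    return np.column_stack([cl, 60000.0 / cl])


def snrt(
    last_stimulus_ms: float,
    post_pacing_activations: Sequence[float],
    pcl_ms: float = 100.0,
    n_pulses: int = 12,
    timeout_ms: float = 3000.0,
) -> SnrtResult:
    """Sinus node recovery time after an overdrive drive train.

    SNRT is the interval from the last pacing stimulus to the first
    spontaneous activation. If no spontaneous beat occurs within
    ``timeout_ms`` the result is censored.
    """
    spontaneous = sorted(t for t in post_pacing_activations if t > last_stimulus_ms)
    if not spontaneous or spontaneous[0] - last_stimulus_ms > timeout_ms:
        return SnrtResult(snrt_ms=None, censored=True, pcl_ms=pcl_ms, n_pulses=n_pulses)
    return SnrtResult(
        snrt_ms=spontaneous[0] - last_stimulus_ms,
        censored=False,
        pcl_ms=pcl_ms,
        n_pulses=n_pulses,
    )
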