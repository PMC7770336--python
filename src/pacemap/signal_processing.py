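"""Movie conditioning: spatial neighborhood mean, zero-phase temporal
low-pass, and per-beat per-pixel amplitude normalization.

The processing order used by the pipeline is spatial filter -> temporal
filter -> beat segmentation -> per-beat normalization. The spatial filter
is an unweighted k x k box mean restricted to in-mask pixels, with
truncated windows at the frame edges. The temporal filter is a zero-phase
(forward-backward) Butterworth low-pass, so activation times are not
phase-shifted; its DC gain is exactly 1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .types import BeatWindow, MovieStack, NormalizedBeat

__all__ = [
    "spatial_filter",
    "temporal_filter",
    "normalize_beats",
    "estimate_noise_sd",
]


def spatial_filter(
    movie: MovieStack, kernel_px: int = 3, mask: Optional[np.ndarray] = None
) -> MovieStack:
    """Replace each frame by its k x k in-mask neighborhood mean.

    Pixels outside the mask are passed through unchanged; windows at edges
    (or abutting the mask) average only the valid neighbors present.
    """
    k = int(kernel_px)
    if k % 2 == 0:
        raise ValueError("kernel_px must be odd")
    if k < 3:
        raise ValueError("kernel_px must be >= 3")
    h, w = movie.frame_shape
    if k > min(h, w):
        raise ValueError("kernel_px larger than the frame")
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    frames = movie.frames.astype(float, copy=False)
    maskf = mask.astype(float)
    num = ndimage.uniform_filter(frames * maskf[None], size=(1, k, k), mode="constant")
    den = ndimage.uniform_filter(maskf, size=(k, k), mode="constant")
    out = frames.copy()
    valid = mask & (den > 0)
    out[:, valid] = num[:, valid] / den[valid]
    return MovieStack(
        frames=out,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_pitch_mm=movie.pixel_pitch_mm,
        polarity=movie.polarity,
    )


def temporal_filter(
    movie: MovieStack, cutoff_hz: float = 150.0, order: int = 3
) -> MovieStack:
    """Zero-phase Butterworth low-pass along time, per pixel.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the squared Butterworth magnitude and the phase is zero.
    """
    nyquist = movie.frame_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(int(order), cutoff_hz, btype="low", fs=movie.frame_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, movie.frames.astype(float, copy=False), axis=0)
    return MovieStack(
        frames=filtered,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_pitch_mm=movie.pixel_pitch_mm,
        polarity=movie.polarity,
    )


def estimate_noise_sd(window_data: np.ndarray) -> np.ndarray:
    """Per-pixel noise sd from the diastolic portion of one beat window.

    Diastole is taken as the frames in the lowest quartile of each pixel's
    range; the robust sd is 1.4826 x the median absolute deviation of
    those samples about their median.
    """
    lo = window_data.min(axis=0)
    rng = window_data.max(axis=0) - lo
    diastolic = np.where(window_data <= lo + 0.25 * rng, window_data, np.nan)
    med = np.nanmedian(diastolic, axis=0)
    mad = np.nanmedian(np.abs(diastolic - med), axis=0)
    return 1.4826 * mad


def normalize_beats(
    movie: MovieStack,
    windows: list[BeatWindow],
    mask: Optional[np.ndarray] = None,
    amplitude_floor: Optional[float] = None,
) -> list[NormalizedBeat]:
    """Min-max scale each pixel's trace to [0, 1] within each beat window.

    Inverted-polarity movies are negated first so depolarization is
    rising. Pixels whose within-window amplitude falls below the floor
    (default: 2x the estimated diastolic noise sd) are flagged invalid and
    set to NaN rather than divided by a vanishing range.
    """
    if not windows:
        raise ValueError("empty window list")
    h, w = movie.frame_shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    sign = -1.0 if movie.polarity == "inverted" else 1.0
    out: list[NormalizedBeat] = []
    for win in windows:
        if win.end_frame >= movie.n_frames:
            raise ValueError("beat window extends past the movie")
        data = sign * movie.frames[win.start_frame : win.end_frame + 1].astype(float)
        lo = data.min(axis=0)
        amp = data.max(axis=0) - lo
        if amplitude_floor is None:
            floor = 2.0 * estimate_noise_sd(data)
        else:
            floor = np.full((h, w), float(amplitude_floor))
        valid = mask & (amp > floor) & (amp > 0)
        norm = np.full_like(data, np.nan)
        norm[:, valid] = (data[:, valid] - lo[valid]) / amp[valid]
        out.append(NormalizedBeat(window=win, data=norm, valid=valid))
    return out
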