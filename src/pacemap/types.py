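"""Core data containers shared across the pipeline.

Conventions: pixel coordinates are (row, col), 0-based, origin at the
top-left of the frame; times are in milliseconds; rates in beats/min;
distances in millimetres via the camera pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

POSITIVE = "positive"
INVERTED = "inverted"
POLARITIES = (POSITIVE, INVERTED)


@dataclass
class Landmarks:
    """Anatomical reference pixels of the right-atrial preparation.

    ``ivc_px`` and ``svc_px`` are the pixels marking the inferior and
    superior vena cava; they define the normalized pacemaker axis
    (y = 0 at the IVC, y = 1 at the SVC).
    """

    ivc_px: tuple[int, int]
    svc_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.ivc_px = (int(self.ivc_px[0]), int(self.ivc_px[1]))
        self.svc_px = (int(self.svc_px[0]), int(self.svc_px[1]))
        if self.ivc_px == self.svc_px:
            raise ValueError("degenerate axis: ivc_px == svc_px")

    def validate_bounds(self, height_px: int, width_px: int) -> None:
        for name, (r, c) in (("ivc_px", self.ivc_px), ("svc_px", self.svc_px)):
            if not (0 <= r < height_px and 0 <= c < width_px):
                raise ValueError(
                    f"landmark {name}={(r, c)} outside {height_px}x{width_px} frame"
                )

    def to_dict(self) -> dict:
        return {"ivc_px": list(self.ivc_px), "svc_px": list(self.svc_px)}


@dataclass
class TissueGeometry:
    """Imaged field of view: grid size, pixel pitch, tissue mask, landmarks."""

    height_px: int
    width_px: int
    pixel_pitch_mm: float
    landmarks: Landmarks
    mask: Optional[np.ndarray] = None  # boolean H x W; None = all tissue

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("grid must have positive dimensions")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.mask is None:
            self.mask = np.ones((self.height_px, self.width_px), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.height_px, self.width_px):
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("mask has no tissue pixels")
        self.landmarks.validate_bounds(self.height_px, self.width_px)


@dataclass
class PacemakerFocus:
    """A point source of automaticity with condition-dependent cycle lengths.

    ``intrinsic_cl_ms`` maps a condition label (e.g. "baseline", "ACh",
    "ISO") to the focus's spontaneous cycle length under that condition.
    A focus fires at ``first_firing_ms + k * cl`` for k = 0, 1, ...
    """

    position_px: tuple[int, int]
    intrinsic_cl_ms: Mapping[str, float]
    first_firing_ms: float = 0.0

    def __post_init__(self) -> None:
        self.position_px = (int(self.position_px[0]), int(self.position_px[1]))
        if not self.intrinsic_cl_ms:
            raise ValueError("focus needs at least one condition cycle length")
        for cond, cl in self.intrinsic_cl_ms.items():
            if cl <= 0:
                raise ValueError(f"cycle length for {cond!r} must be positive")

    def cycle_length(self, condition: str) -> float:
        try:
            return float(self.intrinsic_cl_ms[condition])
        except KeyError:
            raise KeyError(
                f"focus has no cycle length for condition {condition!r}"
            ) from None


@dataclass
class OAPTemplate:
    """Stylized optical action potential: linear upstroke, exponential
    repolarization with time constant (apd_ms - upstroke_ms) / 3."""

    upstroke_ms: float = 5.0
    apd_ms: float = 60.0
    amplitude: float = 1.0
    resting_level: float = 0.0

    def __post_init__(self) -> None:
        if self.upstroke_ms <= 0 or self.apd_ms <= 0:
            raise ValueError("upstroke_ms and apd_ms must be positive")
        if self.upstroke_ms >= self.apd_ms:
            raise ValueError("upstroke_ms must be shorter than apd_ms")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def tau_ms(self) -> float:
        return (self.apd_ms - self.upstroke_ms) / 3.0

    @property
    def support_ms(self) -> float:
        """Time past the upstroke onset after which the deflection is ~0."""
        return self.upstroke_ms + 6.0 * self.tau_ms

    def waveform(self, phase_ms: np.ndarray) -> np.ndarray:
        """Deflection above resting level at ``phase_ms`` after upstroke onset."""
        phase = np.asarray(phase_ms, dtype=float)
        out = np.zeros_like(phase)
        rising = (phase >= 0) & (phase < self.upstroke_ms)
        out[rising] = phase[rising] / self.upstroke_ms
        falling = phase >= self.upstroke_ms
        out[falling] = np.exp(-(phase[falling] - self.upstroke_ms) / self.tau_ms)
        return self.amplitude * out


@dataclass
class SimulationConfig:
    """Everything needed to render one synthetic voltage-dye recording."""

    geometry: TissueGeometry
    foci: list[PacemakerFocus]
    conduction_velocity_mm_per_ms: float
    template: OAPTemplate
    noise_sd: float
    frame_rate_hz: float
    duration_ms: float
    polarity: str = POSITIVE
    seed: int = 0
    condition: str = "baseline"
    refractory_ms: Optional[float] = None  # None -> template apd_ms

    def __post_init__(self) -> None:
        if not self.foci:
            raise ValueError("no pacemaker source")
        if self.conduction_velocity_mm_per_ms <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.frame_rate_hz <= 0 or self.duration_ms <= 0:
            raise ValueError("frame rate and duration must be positive")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        for f in self.foci:
            r, c = f.position_px
            if not (
                0 <= r < self.geometry.height_px
                and 0 <= c < self.geometry.width_px
                and self.geometry.mask[r, c]
            ):
                raise ValueError(f"focus at {f.position_px} outside tissue mask")

    @property
    def effective_refractory_ms(self) -> float:
        if self.refractory_ms is not None:
            return float(self.refractory_ms)
        return self.template.apd_ms


@dataclass
class GroundTruth:
    """Generative truth accompanying a rendered movie."""

    beat_times_ms: dict[int, np.ndarray]  # focus index -> firing times
    beat_onsets_ms: np.ndarray  # accepted beat onset per beat
    winning_focus: np.ndarray  # focus index per beat
    true_activation_field: np.ndarray  # (n_beats, H, W), ms; NaN off-mask
    true_cl_ms: np.ndarray  # onset-to-onset interval per beat (NaN for last)

    @property
    def n_beats(self) -> int:
        return len(self.beat_onsets_ms)


@dataclass
class MovieStack:
    """A fluorescence recording: frames (T, H, W) plus acquisition metadata."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_pitch_mm: float
    polarity: str = POSITIVE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T>=2, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms


@dataclass
class BeatWindow:
    """Frame span of one beat: diastolic minimum to diastolic minimum."""

    start_frame: int
    end_frame: int
    peak_frame: int
    t_ref_ms: float

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must precede end_frame")
        if not self.start_frame <= self.peak_frame <= self.end_frame:
            raise ValueError("peak_frame must lie inside the window")


@dataclass
class NormalizedBeat:
    """One beat's per-pixel traces min-max scaled to [0, 1]."""

    window: BeatWindow
    data: np.ndarray  # (Tw, H, W); NaN where invalid
    valid: np.ndarray  # (H, W) bool


@dataclass
class ActivationMap:
    """Per-pixel AP50 activation times (ms, relative to the window start)."""

    times_ms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.times_ms.shape != self.valid.shape:
            raise ValueError("times and valid grids must share a shape")


@dataclass
class LeadingSiteRecord:
    """One beat's neighbor-validated earliest-activation site."""

    beat_idx: int
    pixel: tuple[int, int]
    t_act_ms: float
    cl_ms: float
    hr_bpm: float
    condition: str = "baseline"


@dataclass
class AxisCoordinates:
    """Position on the normalized IVC(0) -> SVC(1) axis.

    ``y_au`` is deliberately not clamped to [0, 1]: sites projecting
    beyond the venae cavae flag annotation problems and must stay visible.
    """

    y_au: float
    x_mm: float


@dataclass
class ClusterSummary:
    """Two-cluster description of pooled leading-site positions."""

    assignments: np.ndarray  # per record: "superior" | "inferior"
    mu_sup: float
    sigma_sup: float
    mu_inf: float
    sigma_inf: float
    beta0: float
    beta1: float
    separation_flag: bool

    def to_dict(self) -> dict:
        return {
            "mu_sup": self.mu_sup,
            "sigma_sup": self.sigma_sup,
            "mu_inf": self.mu_inf,
            "sigma_inf": self.sigma_inf,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "separation_flag": self.separation_flag,
            "n_superior": int(np.sum(self.assignments == "superior")),
            "n_inferior": int(np.sum(self.assignments == "inferior")),
        }


@dataclass
class DominanceCall:
    """Per-heart classification of which pacemaker region drives the beats."""

    heart_id: str
    call: str  # "sSAN_only" | "iSAN_only" | "dual"
    fraction_superior: float


@dataclass
class SnrtResult:
    """Sinus node recovery time after an overdrive-pacing drive train."""

    snrt_ms: Optional[float]
    censored: bool
    pcl_ms: float = 100.0
    n_pulses: int = 12
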