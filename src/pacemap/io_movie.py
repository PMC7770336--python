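"""Reading and writing movie stacks, landmark annotations, and result tables.

Two movie dialects are supported, both with a JSON metadata file:

* multi-frame TIFF ``<stem>.tif`` + sidecar ``<stem>.json``
* raw little-endian binary ``<stem>.bin`` (frame-major) whose JSON header
  additionally records ``dtype`` and ``shape`` [T, H, W]

The JSON carries ``frame_rate_hz``, ``pixel_pitch_mm`` and ``polarity``
(required), plus optional ``landmarks`` ({"ivc_px": [r, c], "svc_px": [r, c]}).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .types import Landmarks, MovieStack

__all__ = [
    "read_movie",
    "write_movie",
    "read_landmarks",
    "write_landmarks",
    "read_sidecar",
    "write_beats_table",
    "read_beats_table",
]

REQUIRED_META = ("frame_rate_hz", "pixel_pitch_mm", "polarity")

BEATS_COLUMNS = [
    "beat_idx",
    "t_peak_ms",
    "cl_ms",
    "hr_bpm",
    "lead_row",
    "lead_col",
    "t_act_ms",
    "y_au",
    "x_mm",
    "condition",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata file {sidecar} not found; movies need a JSON sidecar "
            f"with keys {list(REQUIRED_META)}"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing metadata keys: {missing}")
    return meta


def write_movie(movie: MovieStack, path: str | Path, landmarks: Optional[Landmarks] = None) -> Path:
    """Write a movie as TIFF (+JSON sidecar) or raw binary (+JSON header).

    The dialect is chosen by the suffix: ``.tif``/``.tiff`` or ``.bin``.
    Returns the path of the movie payload.
    """
    path = Path(path)
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_pitch_mm": movie.pixel_pitch_mm,
        "polarity": movie.polarity,
    }
    if landmarks is not None:
        meta["landmarks"] = landmarks.to_dict()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames, photometric="minisblack")
    elif path.suffix == ".bin":
        arr = np.ascontiguousarray(movie.frames)
        le = arr.dtype.newbyteorder("<")
        arr.astype(le, copy=False).tofile(path)
        meta["dtype"] = le.str
        meta["shape"] = list(arr.shape)
    else:
        raise ValueError(f"unsupported movie suffix {path.suffix!r} (use .tif or .bin)")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_movie` (either dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file {path} not found")
    meta = read_sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix == ".bin":
        for key in ("dtype", "shape"):
            if key not in meta:
                raise ValueError(f"raw-binary header missing key {key!r}")
        frames = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        expected = int(np.prod(meta["shape"]))
        if frames.size != expected:
            raise ValueError(
                f"payload {path} has {frames.size} values, header shape "
                f"{meta['shape']} implies {expected}"
            )
        frames = frames.reshape(meta["shape"])
    else:
        raise ValueError(f"unsupported movie suffix {path.suffix!r} (use .tif or .bin)")
    if float(meta["frame_rate_hz"]) <= 0:
        raise ValueError("nonpositive frame rate in metadata")
    return MovieStack(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
        polarity=str(meta["polarity"]),
    )


def movie_landmarks(path: str | Path) -> Optional[Landmarks]:
    """Landmarks embedded in a movie's sidecar, if present."""
    meta = read_sidecar(Path(path))
    if "landmarks" not in meta:
        return None
    lm = meta["landmarks"]
    return Landmarks(ivc_px=tuple(lm["ivc_px"]), svc_px=tuple(lm["svc_px"]))


def write_landmarks(landmarks: Landmarks, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(landmarks.to_dict(), fh, indent=1)
    return path


def read_landmarks(path: str | Path, frame_shape: Optional[tuple[int, int]] = None) -> Landmarks:
    """Read a landmark JSON ({"ivc_px": [r, c], "svc_px": [r, c]}).

    If ``frame_shape`` is given, landmarks are checked to lie inside it.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in ("ivc_px", "svc_px") if k not in data]
    if missing:
        raise ValueError(f"landmark file {path} missing keys: {missing}")
    lm = Landmarks(ivc_px=tuple(data["ivc_px"]), svc_px=tuple(data["svc_px"]))
    if frame_shape is not None:
        lm.validate_bounds(*frame_shape)
    return lm


def write_beats_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-beat results table (beats.csv schema)."""
    path = Path(path)
    cols = [c for c in BEATS_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, index=False)
    return path


def read_beats_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
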