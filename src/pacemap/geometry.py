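"""Projection of leading-pacemaker pixels onto the normalized IVC -> SVC
axis (y, arbitrary units: 0 at the IVC, 1 at the SVC) and the signed
perpendicular offset (x, mm).

Two axis modes are provided: a straight segment between the two landmark
pixels, and a polyline traced through ordered waypoints (for curved
preparations where the axis follows the crista terminalis); the polyline
is arc-length normalized. ``y_au`` is never clamped: projections outside
[0, 1] signal annotation problems and are kept visible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import AxisCoordinates, Landmarks

__all__ = ["project_site", "PolylineAxis"]


def project_site(
    pixel: tuple[float, float],
    landmarks: Landmarks,
    pixel_pitch_mm: float,
) -> AxisCoordinates:
    """Project a pixel onto the straight IVC->SVC axis.

    ``y_au`` is the scalar projection of (pixel - ivc) onto the axis unit
    vector, divided by the axis length. ``x_mm`` is the signed
    perpendicular component scaled by the pixel pitch; the positive side
    follows the axis vector rotated by +90 degrees, i.e. the normal
    n = (-u_col, u_row) in (row, col) coordinates.
    """
    ivc = np.asarray(landmarks.ivc_px, dtype=float)
    svc = np.asarray(landmarks.svc_px, dtype=float)
    axis = svc - ivc
    length = float(np.hypot(*axis))
    if length == 0.0:
        raise ValueError("degenerate axis: ivc == svc")
    u = axis / length
    d = np.asarray(pixel, dtype=float) - ivc
    y_au = float(d @ u) / length
    n = np.array([-u[1], u[0]])
    x_mm = float(d @ n) * pixel_pitch_mm
    return AxisCoordinates(y_au=y_au, x_mm=x_mm)


class PolylineAxis:
    """Arc-length normalized axis through ordered waypoints (IVC first,
    SVC last); a pixel projects onto its nearest point of the polyline."""

    def __init__(self, waypoints_px: Sequence[tuple[float, float]], pixel_pitch_mm: float):
        pts = np.asarray(waypoints_px, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("polyline needs >= 2 (row, col) waypoints")
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len == 0):
            raise ValueError("degenerate axis: zero-length polyline segment")
        self.points = pts
        self.seg = seg
        self.seg_len = seg_len
        self.cum_len = np.concatenate([[0.0], np.cumsum(seg_len)])
        self.total_len = float(self.cum_len[-1])
        self.pixel_pitch_mm = float(pixel_pitch_mm)

    def project(self, pixel: tuple[float, float]) -> AxisCoordinates:
        p = np.asarray(pixel, dtype=float)
        best = None
        for i in range(len(self.seg)):
            a = self.points[i]
            t = float(np.clip((p - a) @ self.seg[i] / self.seg_len[i] ** 2, 0.0, 1.0))
            foot = a + t * self.seg[i]
            d = p - foot
            dist = float(np.hypot(*d))
            u = self.seg[i] / self.seg_len[i]
            side = float(d @ np.array([-u[1], u[0]]))
            arclen = self.cum_len[i] + t * self.seg_len[i]
            cand = (dist, arclen, side)
            if best is None or dist < best[0] - 1e-12:
                best = cand
        dist, arclen, side = best
        x = np.copysign(dist, side if side != 0 else 1.0)
        return AxisCoordinates(
            y_au=arclen / self.total_len, x_mm=x * self.pixel_pitch_mm
        )
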