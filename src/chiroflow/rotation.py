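"""Nuclear rotation from two tracked landmarks (nucleoli).

The orientation of the nucleus is the angle of the line joining two tracked
nucleoli in the image plane (y down).  The cumulative rotation angle is the
sum of frame-to-frame orientation increments, each wrapped into the
principal interval, so full turns accumulate instead of wrapping; clockwise
rotation on screen (clockwise viewed from the dorsal side) counts positive.

Two modes: ``vector`` treats the pair as ordered (period 360°, the default
— the nucleoli are individually identified in the tracking) and ``line``
treats it as an unordered line (period 180°, robust to label swaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LandmarkTrack", "RotationTrace", "cumulative_angle", "mean_angular_velocity",
           "read_track_csv", "write_track_csv"]


@dataclass(frozen=True)
class LandmarkTrack:
    """Two-landmark trajectory: times (hr) and per-frame positions (image units)."""

    time_hr: np.ndarray
    a_xy: np.ndarray          # (n, 2)
    b_xy: np.ndarray          # (n, 2)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_hr, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        if self.a_xy.shape != (t.size, 2) or self.b_xy.shape != (t.size, 2):
            raise ValueError("landmark arrays must have shape (n_frames, 2)")
        if self.valid is not None and self.valid.shape != t.shape:
            raise ValueError("valid flags must match the number of frames")


@dataclass(frozen=True)
class RotationTrace:
    """Cumulative rotation angle (deg, clockwise positive, theta(t0) = 0)."""

    time_hr: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self) -> None:
        step = np.abs(np.diff(self.theta_deg))
        if step.size and step.max() >= 180.0:
            raise ValueError("per-frame rotation reaches 180°; sampling too sparse to unwrap")


def cumulative_angle(
    track: LandmarkTrack,
    mode: str = "vector",
    min_separation: float = 1e-9,
    max_gap: int = 5,
) -> RotationTrace:
    """Accumulate the rotation of the landmark pair over time.

    Frame orientations come from the two-argument arctangent of ``B - A`` in
    image coordinates; successive differences are wrapped into (-180°, 180°]
    (``vector`` mode) or (-90°, 90°] (``line`` mode) and summed.  Frames
    with coincident landmarks (separation below ``min_separation``) are
    dropped with a warning; more than ``max_gap`` consecutive dropped frames
    is an error.
    """
    if mode not in ("vector", "line"):
        raise ValueError("mode must be 'vector' or 'line'")
    d = track.b_xy - track.a_xy
    sep = np.hypot(d[:, 0], d[:, 1])
    ok = sep > min_separation
    if track.valid is not None:
        ok &= track.valid.astype(bool)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 valid frames")
    dropped = np.flatnonzero(~ok)
    if dropped.size:
        import warnings

        warnings.warn(f"dropped {dropped.size} frame(s) with coincident/invalid landmarks")
        runs = np.split(dropped, np.flatnonzero(np.diff(dropped) > 1) + 1)
        if max(len(r) for r in runs) > max_gap:
            raise ValueError(f"gap of more than {max_gap} consecutive invalid frames")

    t = np.asarray(track.time_hr, float)[ok]
    ang = np.degrees(np.arctan2(d[ok, 1], d[ok, 0]))  # y down: increases clockwise on screen
    period = 360.0 if mode == "vector" else 180.0
    inc = np.diff(ang)
    inc = (inc + period / 2.0) % period - period / 2.0   # wrap into (-p/2, p/2]
    inc[inc == -period / 2.0] = period / 2.0
    theta = np.concatenate([[0.0], np.cumsum(inc)])
    return RotationTrace(time_hr=t, theta_deg=theta)


def mean_angular_velocity(trace: RotationTrace, window: tuple) -> float:
    """Average angular velocity (deg/hr) over ``window = (t_start, t_end)``.

    Endpoint angles are linearly interpolated between frames, so the window
    need not align with the sampling times.
    """
    t0, t1 = float(window[0]), float(window[1])
    t = trace.time_hr
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"window [{t0}, {t1}] outside trace support [{t[0]}, {t[-1]}]")
    th0 = float(np.interp(t0, t, trace.theta_deg))
    th1 = float(np.interp(t1, t, trace.theta_deg))
    return (th1 - th0) / (t1 - t0)


def write_track_csv(path, track: LandmarkTrack) -> None:
    pd.DataFrame(
        {
            "time_hr": track.time_hr,
            "ax": track.a_xy[:, 0], "ay": track.a_xy[:, 1],
            "bx": track.b_xy[:, 0], "by": track.b_xy[:, 1],
            "valid": (track.valid if track.valid is not None else np.ones(track.time_hr.size)).astype(int),
        }
    ).to_csv(path, index=False)


def read_track_csv(path) -> LandmarkTrack:
    df = pd.read_csv(path)
    return LandmarkTrack(
        time_hr=df["time_hr"].to_numpy(float),
        a_xy=df[["ax", "ay"]].to_numpy(float),
        b_xy=df[["bx", "by"]].to_numpy(float),
        valid=df["valid"].to_numpy(bool) if "valid" in df else None,
    )
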