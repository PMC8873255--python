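"""Geometric shape and temporal features of individual segments.

Shape features follow the tortuosity idea: how much and how sharply a
path turns.  Turning is measured by first-order angles between
consecutive displacement vectors and second-order angles between
stride-2 displacement vectors; averaging the two magnitudes damps GPS
jitter.  The temporal feature is the sequence of stop durations: maximal
time windows during which the position stays within a small radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TWO_PI = 2.0 * np.pi


@dataclass
class TurningAngles:
    """First/second-order turning angles of one segment, in degrees.

    ``theta1[k]`` is the counterclockwise rotation, in [0, 360), from the
    displacement vector arriving at interior sample k+1 to the one
    leaving it.  ``theta2`` is the analogue on stride-2 vectors and is
    undefined at the two samples adjacent to each end.  ``theta_avg`` is
    the mean of the two angle magnitudes (each folded into [0, 180]) at
    the samples where both orders exist.
    """

    theta1: np.ndarray
    theta2: np.ndarray
    theta_avg: np.ndarray


def _merge_duplicates(xy: np.ndarray) -> np.ndarray:
    """Drop consecutive exactly-repeated points (zero-length vectors)."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        return xy
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.any(xy[1:] != xy[:-1], axis=1)
    return xy[keep]


def _ccw_angles(v_in: np.ndarray, v_out: np.ndarray) -> np.ndarray:
    """Counterclockwise rotation from v_in to v_out, degrees in [0, 360)."""
    cross = v_in[:, 0] * v_out[:, 1] - v_in[:, 1] * v_out[:, 0]
    dot = np.sum(v_in * v_out, axis=1)
    ang = np.arctan2(cross, dot)  # (-pi, pi]
    return np.degrees(np.mod(ang, _TWO_PI))


def fold(theta: np.ndarray) -> np.ndarray:
    """Angle magnitude: map [0, 360) to [0, 180] via min(theta, 360-theta)."""
    theta = np.asarray(theta, dtype=float)
    return np.minimum(theta, 360.0 - theta)


def turning_angles(xy: np.ndarray) -> TurningAngles:
    """Turning angles of a polyline, duplicates merged first.

    With fewer than 3 distinct consecutive points all angle arrays are
    empty.
    """
    xy = _merge_duplicates(xy)
    n = len(xy)
    if n < 3:
        empty = np.empty(0)
        return TurningAngles(empty, empty.copy(), empty.copy())
    v = np.diff(xy, axis=0)
    theta1 = _ccw_angles(v[:-1], v[1:])  # at samples 1 .. n-2
    if n < 5:
        theta2 = np.empty(0)
        theta_avg = np.empty(0)
    else:
        w_in = xy[2:-2] - xy[:-4]   # <x_{i-2}, x_i>
        w_out = xy[4:] - xy[2:-2]   # <x_i, x_{i+2}>
        theta2 = _ccw_angles(w_in, w_out)  # at samples 2 .. n-3
        theta_avg = 0.5 * (fold(theta1[1:-1]) + fold(theta2))
    return TurningAngles(theta1, theta2, theta_avg)


def segment_complexity(angles: TurningAngles, threshold: float = 120.0) -> int:
    """Number of samples whose averaged turn magnitude exceeds ``threshold`` deg.

    Because only magnitudes enter, the count is invariant to reversing
    the direction of travel.
    """
    return int(np.count_nonzero(angles.theta_avg > threshold))


def total_turning_angle(angles: TurningAngles) -> float:
    """Sum of sines of the first-order turning angles.

    With the counterclockwise [0, 360) convention, turns beyond 180
    degrees (i.e. clockwise turns) contribute negatively, so the sum is
    signed: positive for counterclockwise-majority turning.
    """
    return float(np.sum(np.sin(np.radians(angles.theta1))))


def radius_of_gyration(xy: np.ndarray) -> float:
    """Root-mean-square distance of the samples from their centroid (m)."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        raise ValueError("radius of gyration of an empty segment")
    d = xy - xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class StopList:
    """Ordered stop durations (s) detected within one segment."""

    durations: list[float]

    @property
    def count(self) -> int:
        return len(self.durations)


def detect_stops(
    time: np.ndarray,
    xy: np.ndarray,
    static_radius: float = 10.0,
    min_stop_duration: float = 60.0,
) -> StopList:
    """Detect stops: windows staying within ``static_radius`` of their anchor.

    Greedy scan: anchor at the current sample, extend the window while
    every sample stays within the radius of the anchor; when the
    window's time span reaches ``min_stop_duration`` record it and
    resume after the window, otherwise advance the anchor by one sample.
    "Not changing location" is deliberately a radius test — raw GPS
    positions jitter even when the person is still.
    """
    time = np.asarray(time, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n = len(time)
    if n == 0:
        return StopList([])
    leave = _first_exit(xy, static_radius)
    durations: list[float] = []
    i = 0
    while i < n:
        j = leave[i]  # first sample outside the radius of anchor i
        span = time[j - 1] - time[i]
        if span >= min_stop_duration:
            durations.append(float(span))
            i = j
        else:
            i += 1
    return StopList(durations)


def _first_exit(xy: np.ndarray, radius: float) -> np.ndarray:
    """leave[i]: first index j > i with |xy[j] - xy[i]| > radius, else n."""
    n = len(xy)
    leave = np.empty(n, dtype=np.int64)
    if n <= 1500:
        d2 = np.sum((xy[None, :, :] - xy[:, None, :]) ** 2, axis=2)
        out = d2 > radius * radius
        for i in range(n):
            hits = np.flatnonzero(out[i, i + 1 :])
            leave[i] = i + 1 + hits[0] if len(hits) else n
    else:
        r2 = radius * radius
        for i in range(n):
            j = i + 1
            leave[i] = n
            while j < n:
                block = np.sum((xy[j : j + 256] - xy[i]) ** 2, axis=1) > r2
                hit = np.flatnonzero(block)
                if len(hit):
                    leave[i] = j + hit[0]
                    break
                j += 256
    return leave
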