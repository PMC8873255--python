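"""Seeded synthetic GPS cohorts with the structure the analysis assumes.

The study data this pipeline targets (outdoor GPS traces of Alzheimer's
patients and matched controls) are private, so every stage is exercised
on synthetic cohorts instead.  Each participant lives on a private
plane: a home, a persistent set of destinations at group-scaled
distances, and persistent piecewise-linear routes.  Outings are
home-anchored round trips — out along a route, a stationary dwell and a
short stroll at the destination, back along the route — sampled at the
participant's nominal interval (3 s or 5 s) and perturbed by isotropic
Gaussian GPS noise.

Group contrasts are injected only through the configured effect
parameters: patients get fewer and closer destinations and a higher
probability of replaying an existing route (lower entropy, higher
segment similarity, shorter distance from home), and their accompanied
outings get a counterclockwise heading drift, hairpin side-detours and
extra mid-route pauses (higher segment complexity, total turning angle
and stop count).  With the contrasts switched off
(:func:`null_config`), outing-level feature values are drawn from the
same distributions in both groups — destination distances follow a
deterministic per-rank ladder shared by all participants of a group, so
that pooled per-segment values behave approximately like i.i.d. samples
and two-sample tests on them are approximately calibrated.

Every quantity is drawn from a generator seeded through a single master
seed; regenerating a cohort with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ALONE,
    ACCOMPANIED,
    EARTH_RADIUS_M,
    OutingAnnotation,
    Trace,
    write_trace,
)

_DEG = math.pi / 180.0
#: 2019-03-04T00:00:00Z, an arbitrary fixed cohort start date.
_EPOCH0 = 1551657600.0


@dataclass
class CohortConfig:
    """Cohort layout and effect parameters (defaults: the study conditions).

    The cohort mirrors the study design: 18 controls and 15 patients
    tracked for two weeks, with 13 controls and 8 patients logged at
    3 s and the remainder at 5 s.  Effect parameters encode the group
    contrasts the analysis is meant to detect; ``dest_scale_patient`` is
    a quarter of the control scale, and accompanied-outing shape effects
    apply to patients only.
    """

    n_controls: int = 18
    n_patients: int = 15
    days: int = 14
    fast_sampling_controls: int = 13   # participants sampled at 3 s; rest 5 s
    fast_sampling_patients: int = 8
    gps_noise_sd: float = 5.0          # metres, stationary SD of positional error
    noise_corr_time: float = 60.0      # seconds; AR(1) error decay time (0 = white)
    home_spacing: float = 5000.0       # metres between neighbouring homes
    min_outings_per_day: int = 1
    max_outings_per_day: int = 4
    # mobility-domain contrasts
    n_destinations_control: int = 10
    n_destinations_patient: int = 4
    dest_scale_control: float = 4000.0   # metres, exponential-ladder scale
    dest_scale_patient: float = 1000.0
    min_dest_distance: float = 600.0   # >= ~6 grid cells: route identity resolvable
    zipf_exponent: float = 1.0
    route_reuse_control: float = 0.08
    route_reuse_patient: float = 0.9
    # transport pace: controls mix walking with fast modes; patients keep
    # to walking/cycling pace, which also makes the shape of their
    # movement resolvable at the 3-5 s sampling interval
    travel_time_lo_control: float = 120.0  # seconds per leg, drawn uniformly
    travel_time_hi_control: float = 300.0
    max_speed_control: float = 40.0        # m/s
    travel_time_lo_patient: float = 180.0
    travel_time_hi_patient: float = 360.0
    max_speed_patient: float = 8.0
    # companionship contrasts (patients only)
    accompanied_fraction: float = 0.5
    accompanied_drift_deg: float = 10.0       # CCW heading drift per 12 m step
    alone_drift_deg: float = 0.0
    accompanied_heading_noise_deg: float = 12.0
    alone_heading_noise_deg: float = 4.0
    accompanied_min_spurs: int = 4            # hairpin side-detours per outing
    accompanied_max_spurs: int = 6
    accompanied_min_loops: int = 4            # CCW circular detours per outing
    accompanied_max_loops: int = 6
    accompanied_min_extra_stops: int = 1
    accompanied_max_extra_stops: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("route_reuse_control", "route_reuse_patient", "accompanied_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.min_outings_per_day < 1 or self.max_outings_per_day < self.min_outings_per_day:
            raise ValueError("bad outings-per-day range")


def null_config(cfg: CohortConfig) -> CohortConfig:
    """The zero-contrast twin of a configuration.

    Patients inherit the control mobility parameters and the
    accompanied-outing shape effects are set to the alone values;
    companionship labels are still drawn so the alone/accompanied
    machinery keeps running.
    """
    return dataclasses.replace(
        cfg,
        # equalise the 3 s / 5 s sampling-rate mix as well: sample-count
        # features (complexity) depend on it, so an unequal mix is a
        # group difference a calibrated null must not contain
        fast_sampling_patients=int(round(cfg.fast_sampling_controls * 15 / 18)),
        n_destinations_patient=cfg.n_destinations_control,
        dest_scale_patient=cfg.dest_scale_control,
        route_reuse_patient=cfg.route_reuse_control,
        travel_time_lo_patient=cfg.travel_time_lo_control,
        travel_time_hi_patient=cfg.travel_time_hi_control,
        max_speed_patient=cfg.max_speed_control,
        # controls are never accompanied, so group-equal means none are:
        # otherwise the alone-only filter halves the patients' segment
        # counts and count-dependent features (entropy, similarity)
        # differ between groups even with all other contrasts at zero
        accompanied_fraction=0.0,
        accompanied_drift_deg=cfg.alone_drift_deg,
        accompanied_heading_noise_deg=cfg.alone_heading_noise_deg,
        accompanied_min_spurs=0,
        accompanied_max_spurs=0,
        accompanied_min_loops=0,
        accompanied_max_loops=0,
        accompanied_min_extra_stops=0,
        accompanied_max_extra_stops=0,
    )


@dataclass
class GroundTruth:
    """Per-outing generator state, for validating the pipeline against."""

    table: pd.DataFrame  # participant_id, outing, day, dest_rank, reused, companionship, start, end
    homes: dict[str, tuple[float, float]]  # participant -> home lat/lon
    destinations: dict[str, np.ndarray]    # participant -> (n_dest, 2) planar xy


@dataclass
class Cohort:
    config: CohortConfig
    traces: list[Trace]
    metadata: dict[str, str]
    annotations: dict[str, list[OutingAnnotation]]
    ground_truth: GroundTruth


# ---------------------------------------------------------------- geometry


def _unit(angle: float | np.ndarray) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-pi, pi]."""
    return (angle + math.pi) % (2 * math.pi) - math.pi


def _steered_path(
    rng: np.random.Generator,
    waypoints: np.ndarray,
    drift_deg: float,
    noise_deg: float,
    step: float = 12.0,
    gain: float = 0.6,
    max_turn_deg: float = 50.0,
    capture: float = 18.0,
) -> np.ndarray:
    """Walk through ``waypoints`` with a steered heading process.

    The heading relaxes towards the bearing of the current waypoint
    (bounded turn per step) plus a deterministic counterclockwise drift
    and Gaussian heading noise; a waypoint is captured within
    ``capture`` metres.  Drift produces leftward-curling paths with
    occasional sharp corrective right turns — the signed turning signal
    of accompanied outings.
    """
    drift = drift_deg * _DEG
    noise = noise_deg * _DEG
    max_turn = max_turn_deg * _DEG
    pos = np.array(waypoints[0], dtype=float)
    pts = [pos.copy()]
    straight = float(np.sum(np.hypot(*np.diff(waypoints, axis=0).T)))
    cap = int(4 * straight / step) + 60
    target_i = 1
    delta = waypoints[target_i] - pos
    psi = math.atan2(delta[1], delta[0])
    for _ in range(cap):
        target = waypoints[target_i]
        delta = target - pos
        if np.hypot(*delta) <= capture:
            target_i += 1
            if target_i >= len(waypoints):
                break
            continue
        bearing = math.atan2(delta[1], delta[0])
        err = _wrap(bearing - psi)
        psi = psi + float(np.clip(gain * err, -max_turn, max_turn))
        psi += drift + rng.normal(0.0, noise)
        pos = pos + step * _unit(psi)
        pts.append(pos.copy())
    pts.append(np.array(waypoints[-1], dtype=float))
    return np.array(pts)


def _insert_spurs(
    rng: np.random.Generator, path: np.ndarray, n_spurs: int, step: float = 12.0
) -> np.ndarray:
    """Insert hairpin side-detours (out-and-back spurs) into a path."""
    for _ in range(n_spurs):
        if len(path) < 12:
            break
        idx = int(rng.integers(4, len(path) - 4))
        base = path[idx]
        local = path[idx + 1] - path[idx - 1]
        heading = math.atan2(local[1], local[0])
        # leftward spur: large CCW departure, reversal, return
        ang = heading + rng.uniform(60.0, 120.0) * _DEG
        length = rng.uniform(70.0, 120.0)
        m = max(2, int(length / step))
        out = base + np.outer(np.arange(1, m + 1) * (length / m), _unit(ang)).reshape(m, 2)
        perp = 2.5 * _unit(ang + math.pi / 2)
        back = out[::-1] + perp
        path = np.concatenate([path[: idx + 1], out, back, path[idx + 1 :]])
    return path


def _insert_loops(
    rng: np.random.Generator, path: np.ndarray, n_loops: int, step: float = 10.0
) -> np.ndarray:
    """Insert small counterclockwise circular detours into a path.

    A CCW circle of m vertices turns left by 360/m degrees at each, so
    each detour adds about m*sin(2*pi/m) ~ +6 to the segment's sum of
    turn sines whatever its radius — the signed-turning signature of
    accompanied outings.
    """
    for _ in range(n_loops):
        if len(path) < 8:
            break
        idx = int(rng.integers(2, len(path) - 2))
        base = path[idx]
        r = rng.uniform(25.0, 40.0)
        a0 = rng.uniform(0.0, 2 * math.pi)
        m = max(8, int(2 * math.pi * r / step))
        ang = a0 + np.linspace(0.0, 2 * math.pi, m + 1)[1:]
        centre = base + r * _unit(a0 + math.pi)
        loop = centre[None, :] + r * np.column_stack([np.cos(ang), np.sin(ang)])
        path = np.concatenate([path[: idx + 1], loop, path[idx + 1 :]])
    return path


def _wander_loop(
    rng: np.random.Generator, centre: np.ndarray, step: float = 12.0
) -> np.ndarray:
    """A small closed stroll around a destination (visits adjacent cells)."""
    r = rng.uniform(25.0, 45.0)
    a0 = rng.uniform(0.0, 2 * math.pi)
    m = max(6, int(2 * math.pi * r / step))
    ang = a0 + np.linspace(0.0, 2 * math.pi, m + 1)
    c = centre + r * _unit(a0 + math.pi)  # circle through the destination
    return c[None, :] + r * np.column_stack([np.cos(ang), np.sin(ang)])


def _leg_profile(
    path: np.ndarray,
    speed: float,
    pauses: list[tuple[int, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex/time profile of a travel leg at constant speed, with pauses."""
    steps = np.hypot(*np.diff(path, axis=0).T)
    times = np.concatenate([[0.0], np.cumsum(steps / speed)])
    pts = list(path)
    ts = list(times)
    if pauses:
        for idx, dur in sorted(pauses, reverse=True):
            pts.insert(idx + 1, pts[idx])
            ts = ts[: idx + 1] + [ts[idx] + dur] + [t + dur for t in ts[idx + 1 :]]
    return np.array(pts), np.array(ts)


def _day_counts(
    rng: np.random.Generator, days: int, lo: int, hi: int
) -> list[int]:
    """Outings per day: between ``lo`` and ``hi``, with a fixed total.

    A shuffled template (alternating mid-range counts, one low and one
    high day swapped in) keeps every participant's total outing count
    identical for a given configuration.  A fixed total means the
    denominator of per-segment fraction features is cohort-wide, so
    pooled feature distributions do not pick up spurious
    participant-level variation from outing-count differences.
    """
    a, b = (lo + hi) // 2, (lo + hi + 1) // 2
    counts = [a if i % 2 == 0 else b for i in range(days)]
    if days >= 2 and lo < a and hi > b:
        counts[0] = lo
        counts[1] = b + (a - lo)  # compensate: total unchanged
    rng.shuffle(counts)
    return counts


def _gps_noise(
    rng: np.random.Generator, n: int, sd: float, dt: float, corr_time: float
) -> np.ndarray:
    """Positional error: stationary AR(1) per axis (slowly drifting fix).

    GPS error is dominated by slowly varying components (atmospheric and
    multipath bias), not white jitter; the AR(1) correlation time
    controls how fast the fix drifts.  ``corr_time=0`` gives white
    noise.
    """
    if n == 0:
        return np.empty((0, 2))
    if sd == 0:
        return np.zeros((n, 2))
    if corr_time <= 0:
        return rng.normal(0.0, sd, size=(n, 2))
    from scipy.signal import lfilter

    phi = math.exp(-dt / corr_time)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=(n, 2))
    innov[0] = rng.normal(0.0, sd, size=2)  # stationary start
    return lfilter([1.0], [1.0, -phi], innov, axis=0)


# ---------------------------------------------------------------- cohort


def _group_params(cfg: CohortConfig, group: str) -> dict:
    patient = group == "patient"
    return {
        "n_dest": cfg.n_destinations_patient if patient else cfg.n_destinations_control,
        "scale": cfg.dest_scale_patient if patient else cfg.dest_scale_control,
        "reuse": cfg.route_reuse_patient if patient else cfg.route_reuse_control,
    }


def _destination_ladder(cfg: CohortConfig, group: str) -> np.ndarray:
    """Deterministic per-rank destination distances (metres).

    Rank k of n sits at the (k+0.5)/n quantile of an exponential with
    the group's scale, floored at ``min_dest_distance``; the ladder is
    identical for every participant of a group.
    """
    p = _group_params(cfg, group)
    q = (np.arange(p["n_dest"]) + 0.5) / p["n_dest"]
    return np.maximum(cfg.min_dest_distance, -p["scale"] * np.log1p(-q))


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()


def generate_participant(
    cfg: CohortConfig,
    group: str,
    participant_id: str,
    seed: np.random.SeedSequence | int,
    sampling_interval: float,
    home_latlon: tuple[float, float],
) -> tuple[Trace, list[OutingAnnotation], pd.DataFrame, np.ndarray]:
    """Generate one participant's trace, diary annotations and ground truth.

    Returns the trace (geographic coordinates, unprojected), the per-
    outing annotations (patients only), the ground-truth outing table
    and the planar destination coordinates.
    """
    rng = np.random.default_rng(seed)
    p = _group_params(cfg, group)
    ladder = _destination_ladder(cfg, group)
    # evenly spaced bearings (randomly rotated and slightly jittered):
    # routes to different destinations then diverge quickly and never
    # share more than a couple of grid cells near home
    spacing = 2 * math.pi / p["n_dest"]
    bearings = (
        rng.uniform(0.0, 2 * math.pi)
        + spacing * rng.permutation(p["n_dest"])
        + rng.uniform(-0.25, 0.25, size=p["n_dest"]) * spacing
    )
    dest_xy = ladder[:, None] * np.column_stack([np.cos(bearings), np.sin(bearings)])
    weights = _zipf_weights(p["n_dest"], cfg.zipf_exponent)
    variants: list[list[tuple]] = [[] for _ in range(p["n_dest"])]

    home = np.zeros(2)
    lat0, lon0 = home_latlon
    m_per_deg_lat = EARTH_RADIUS_M * _DEG
    m_per_deg_lon = EARTH_RADIUS_M * _DEG * math.cos(lat0 * _DEG)

    all_t: list[np.ndarray] = []
    all_xy: list[np.ndarray] = []
    annotations: list[OutingAnnotation] = []
    gt_rows = []
    outing_no = 0

    day_counts = _day_counts(
        rng, cfg.days, cfg.min_outings_per_day, cfg.max_outings_per_day
    )
    for day, n_out in enumerate(day_counts):
        t_cursor = _EPOCH0 + day * 86400.0 + 8 * 3600.0 + rng.uniform(0.0, 3600.0)
        for _ in range(n_out):
            k = int(rng.choice(p["n_dest"], p=weights))
            accompanied = group == "patient" and rng.random() < cfg.accompanied_fraction
            reused = bool(variants[k]) and rng.random() < p["reuse"]
            if reused:
                coarse_out, coarse_ret = variants[k][
                    int(rng.integers(len(variants[k])))
                ]
            else:
                # Fresh route variants are narrow detour loops through a
                # "via" point; the via directions of successive variants
                # sit on an evenly spaced 30-degree ladder around home, so
                # any two variants of a destination run through
                # well-separated corridors and share little beyond the
                # home and destination neighbourhoods (pairwise Jaccard
                # stays decisively below the 0.5 similarity threshold on
                # the 100 m grid), while a replayed variant is trivially
                # similar.  The via ladder and radius are deterministic
                # functions of (rank, variant index) shared by every
                # participant, so all route-persistent feature values
                # (centroid distance, gyration radius, corner turns) sit
                # on the same per-rank grid cohort-wide.
                d = ladder[k]
                v = len(variants[k])
                phi = bearings[k] + math.radians(15.0 + 30.0 * v)
                r_via = max(0.6 * d, 800.0)
                via = r_via * _unit(phi) + rng.normal(0.0, 40.0, 2)
                coarse_out = np.vstack([home, via, dest_xy[k]])
                coarse_ret = np.vstack(
                    [dest_xy[k], via + rng.normal(0.0, 25.0, 2), home]
                )
                variants[k].append((coarse_out, coarse_ret))

            drift = cfg.accompanied_drift_deg if accompanied else cfg.alone_drift_deg
            hnoise = (
                cfg.accompanied_heading_noise_deg
                if accompanied
                else cfg.alone_heading_noise_deg
            )
            out_path = _steered_path(rng, coarse_out, drift, hnoise)
            ret_path = _steered_path(rng, coarse_ret, drift, hnoise)
            extra_stops: list[tuple[str, int, float]] = []
            if accompanied:
                n_spur = int(
                    rng.integers(cfg.accompanied_min_spurs, cfg.accompanied_max_spurs + 1)
                ) if cfg.accompanied_max_spurs > 0 else 0
                out_path = _insert_spurs(rng, out_path, n_spur - n_spur // 2)
                ret_path = _insert_spurs(rng, ret_path, n_spur // 2)
                if cfg.accompanied_max_loops > 0:
                    n_loop = int(
                        rng.integers(
                            cfg.accompanied_min_loops, cfg.accompanied_max_loops + 1
                        )
                    )
                    out_path = _insert_loops(rng, out_path, n_loop - n_loop // 2)
                    ret_path = _insert_loops(rng, ret_path, n_loop // 2)
                if cfg.accompanied_max_extra_stops > 0:
                    n_es = int(
                        rng.integers(
                            cfg.accompanied_min_extra_stops,
                            cfg.accompanied_max_extra_stops + 1,
                        )
                    )
                    for _ in range(n_es):
                        leg = "out" if rng.random() < 0.5 else "ret"
                        path = out_path if leg == "out" else ret_path
                        extra_stops.append(
                            (leg, int(rng.integers(1, len(path) - 1)), rng.uniform(60.0, 100.0))
                        )

            # timing: travel budgets keep (almost) every outing's loop
            # under the 20-min segment ceiling; a rare far accompanied
            # outing may overrun and simply yields no full-loop segment
            len_out = float(np.sum(np.hypot(*np.diff(out_path, axis=0).T)))
            len_ret = float(np.sum(np.hypot(*np.diff(ret_path, axis=0).T)))
            if group == "patient":
                t_lo, t_hi = cfg.travel_time_lo_patient, cfg.travel_time_hi_patient
                v_max = cfg.max_speed_patient
            else:
                t_lo, t_hi = cfg.travel_time_lo_control, cfg.travel_time_hi_control
                v_max = cfg.max_speed_control
            v_out = float(np.clip(len_out / rng.uniform(t_lo, t_hi), 1.2, v_max))
            v_ret = float(np.clip(len_ret / rng.uniform(t_lo, t_hi), 1.2, v_max))
            T_out, T_ret = len_out / v_out, len_ret / v_ret
            if accompanied:  # the detours already are the destination stroll
                wander = np.array([dest_xy[k]])
                T_wander = 0.0
            else:
                wander = _wander_loop(rng, dest_xy[k])
                T_wander = float(np.sum(np.hypot(*np.diff(wander, axis=0).T))) / 1.3
            stop_total = sum(s[2] for s in extra_stops)
            budget = 1100.0 - T_out - T_ret - T_wander - stop_total
            dwell = rng.uniform(60.0, max(61.0, min(480.0, budget)))
            dwell0 = rng.uniform(20.0, 45.0)
            dwell1 = rng.uniform(20.0, 45.0)

            out_pts, out_ts = _leg_profile(
                out_path, v_out, [(i, d_) for leg, i, d_ in extra_stops if leg == "out"]
            )
            ret_pts, ret_ts = _leg_profile(
                ret_path, v_ret, [(i, d_) for leg, i, d_ in extra_stops if leg == "ret"]
            )
            wander_ts = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(wander, axis=0).T) / 1.3)]
            )

            pieces_pts = [
                np.array([home, home]),
                out_pts,
                np.array([dest_xy[k]]),
                wander,
                ret_pts,
                np.array([home, home]),
            ]
            t0 = 0.0
            pieces_ts = []
            for pts_i, ts_i in [
                (pieces_pts[0], np.array([0.0, dwell0])),
                (out_pts, out_ts),
                (pieces_pts[2], np.array([dwell])),
                (wander, wander_ts),
                (ret_pts, ret_ts),
                (pieces_pts[5], np.array([0.0, dwell1])),
            ]:
                pieces_ts.append(ts_i + t0)
                t0 = pieces_ts[-1][-1]
            vt = np.concatenate(pieces_ts)
            vp = np.vstack(pieces_pts)

            t_rel = np.arange(0.0, vt[-1], sampling_interval)
            x = np.interp(t_rel, vt, vp[:, 0])
            y = np.interp(t_rel, vt, vp[:, 1])
            xy = np.column_stack([x, y]) + _gps_noise(
                rng, len(t_rel), cfg.gps_noise_sd, sampling_interval,
                cfg.noise_corr_time,
            )
            t_abs = t_cursor + t_rel
            all_t.append(t_abs)
            all_xy.append(xy)

            comp = ACCOMPANIED if accompanied else ALONE
            if group == "patient":
                annotations.append(
                    OutingAnnotation(
                        participant_id=participant_id,
                        start=float(t_abs[0]),
                        end=float(t_abs[-1]) + sampling_interval,
                        companionship=comp,
                    )
                )
            gt_rows.append(
                {
                    "participant_id": participant_id,
                    "outing": outing_no,
                    "day": day,
                    "dest_rank": k,
                    "reused": reused,
                    "companionship": comp,
                    "start": float(t_abs[0]),
                    "end": float(t_abs[-1]) + sampling_interval,
                }
            )
            outing_no += 1
            t_cursor = t_abs[-1] + rng.uniform(1800.0, 7200.0)

    t = np.concatenate(all_t)
    xy = np.concatenate(all_xy)
    lat = lat0 + xy[:, 1] / m_per_deg_lat
    lon = lon0 + xy[:, 0] / m_per_deg_lon
    trace = Trace(
        participant_id=participant_id,
        group=group,
        time=t,
        lat=lat,
        lon=lon,
        sampling_interval=sampling_interval,
    )
    gt = pd.DataFrame(gt_rows)
    return trace, annotations, gt, dest_xy


def _sampling_intervals(n: int, n_fast: int) -> list[float]:
    n_fast = min(n, n_fast)
    return [3.0] * n_fast + [5.0] * (n - n_fast)


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> Cohort:
    """Generate a full cohort; deterministic given ``cfg.master_seed``."""
    root = np.random.SeedSequence(cfg.master_seed)
    children = root.spawn(cfg.n_controls + cfg.n_patients)

    ids = [f"C{i + 1:02d}" for i in range(cfg.n_controls)] + [
        f"P{i + 1:02d}" for i in range(cfg.n_patients)
    ]
    groups = ["control"] * cfg.n_controls + ["patient"] * cfg.n_patients
    if cfg.n_controls:
        fast_c = int(round(cfg.fast_sampling_controls * cfg.n_controls / 18))
    else:
        fast_c = 0
    fast_p = int(round(cfg.fast_sampling_patients * cfg.n_patients / 15)) if cfg.n_patients else 0
    intervals = _sampling_intervals(cfg.n_controls, fast_c) + _sampling_intervals(
        cfg.n_patients, fast_p
    )

    dlat = cfg.home_spacing / (EARTH_RADIUS_M * _DEG)
    traces, gt_tables = [], []
    metadata: dict[str, str] = {}
    annotations: dict[str, list[OutingAnnotation]] = {}
    homes: dict[str, tuple[float, float]] = {}
    dests: dict[str, np.ndarray] = {}
    for i, (pid, group, child, dt) in enumerate(zip(ids, groups, children, intervals)):
        lat0 = 52.0 + dlat * (i // 6)
        lon0 = 0.1 + dlat / math.cos(lat0 * _DEG) * (i % 6)
        trace, anns, gt, dest_xy = generate_participant(
            cfg, group, pid, child, dt, (lat0, lon0)
        )
        traces.append(trace)
        metadata[pid] = group
        if anns:
            annotations[pid] = anns
        homes[pid] = (lat0, lon0)
        dests[pid] = dest_xy
        gt_tables.append(gt)

    gt_table = (
        pd.concat(gt_tables, ignore_index=True) if gt_tables else pd.DataFrame()
    )
    return Cohort(
        config=cfg,
        traces=traces,
        metadata=metadata,
        annotations=annotations,
        ground_truth=GroundTruth(table=gt_table, homes=homes, destinations=dests),
    )


def _iso(t: float) -> str:
    return (
        pd.to_datetime(round(t * 1e9), utc=True).strftime("%Y-%m-%dT%H:%M:%S.%f")
        + "+00:00"
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort in the external file dialects (trace CSVs + metadata)."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    for trace in cohort.traces:
        write_trace(trace, out / "traces" / f"{trace.participant_id}.csv")
    pd.DataFrame(
        {"participant_id": list(cohort.metadata), "group": list(cohort.metadata.values())}
    ).to_csv(out / "metadata.csv", index=False)
    rows = [
        {
            "participant_id": ann.participant_id,
            "start_iso8601": _iso(ann.start),
            "end_iso8601": _iso(ann.end),
            "companionship": ann.companionship,
        }
        for pid in sorted(cohort.annotations)
        for ann in cohort.annotations[pid]
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "start_iso8601", "end_iso8601", "companionship"]
    ).to_csv(out / "annotations.csv", index=False)
    cohort.ground_truth.table.to_csv(
        out / "ground_truth.csv", index=False, float_format="%.6f"
    )
    (out / "cohort_config.json").write_text(
        json.dumps(dataclasses.asdict(cohort.config), indent=2, sort_keys=True)
    )
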