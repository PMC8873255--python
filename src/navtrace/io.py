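"""Reading, writing and preparing outdoor GPS traces.

A *trace* is one participant's ordered sequence of timestamped positions
recorded by a body-worn GPS logger that is only switched on outside the
home.  Traces therefore consist of short recording *bouts* (outings)
separated by long off-body gaps.  This module handles

* parsing the supported on-disk dialects (a flat CSV point-track format
  and GPX 1.1 track files),
* projecting geographic coordinates to a local metric plane so that all
  downstream geometry can use Euclidean distances in metres,
* splitting a trace into contiguous recording bouts, and
* attaching alone/accompanied companionship labels from a navigation
  diary to individual samples.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres (IUGG).
EARTH_RADIUS_M = 6371008.8

CSV_COLUMNS = [
    "participant_id",
    "timestamp_iso8601",
    "lat",
    "lon",
    "speed_mps",
    "accuracy_pct",
]

GROUPS = ("control", "patient")
ALONE, ACCOMPANIED, UNKNOWN = "alone", "accompanied", "unknown"


@dataclass
class Trace:
    """One participant's ordered GPS samples.

    ``time`` is seconds since the Unix epoch (UTC).  ``xy`` is filled by
    :func:`project_to_plane` and holds planar coordinates in metres, one
    row per sample.  ``speed`` (m/s) and ``accuracy`` (percent) are
    optional columns carried through from the device.
    """

    participant_id: str
    group: str
    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    speed: np.ndarray | None = None
    accuracy: np.ndarray | None = None
    sampling_interval: float = 3.0
    xy: np.ndarray | None = None
    #: (lat0, lon0) centre of the local projection, set by project_to_plane.
    projection_origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if np.any(np.diff(self.time) < 0):
            raise ValueError("samples must be ordered by time")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("latitude/longitude out of bounds")
        if self.xy is not None and len(self.xy) != len(self.time):
            raise ValueError("xy must have one row per sample")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Bout:
    """A maximal run of samples with small inter-sample time gaps."""

    participant_id: str
    start: int  # inclusive sample index
    end: int    # exclusive sample index

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OutingAnnotation:
    """A diary entry: one outing's time interval and companionship."""

    participant_id: str
    start: float  # seconds since epoch, inclusive
    end: float    # exclusive
    companionship: str

    def __post_init__(self) -> None:
        if self.companionship not in (ALONE, ACCOMPANIED):
            raise ValueError(f"bad companionship {self.companionship!r}")
        if not self.end > self.start:
            raise ValueError("annotation interval must have positive length")


def _parse_times(values: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(values, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def read_trace(
    path: str | Path,
    participant_id: str,
    group: str,
    sampling_interval: float = 3.0,
) -> Trace:
    """Read a point-track file (CSV dialect or GPX 1.1) into a :class:`Trace`.

    Samples are returned sorted by time; rows duplicating an earlier
    timestamp are dropped (first occurrence wins) and the number of
    dropped rows is logged.  Malformed rows raise ``ValueError`` naming
    the offending line.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        time, lat, lon = _read_gpx(path)
        speed = accuracy = None
    else:
        time, lat, lon, speed, accuracy = _read_csv(path)
    if len(time) == 0:
        raise ValueError(f"{path}: no samples")

    order = np.argsort(time, kind="stable")
    time, lat, lon = time[order], lat[order], lon[order]
    if speed is not None:
        speed = speed[order]
    if accuracy is not None:
        accuracy = accuracy[order]

    keep = np.ones(len(time), dtype=bool)
    keep[1:] = np.diff(time) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d duplicate-timestamp rows", participant_id, n_dropped
        )
        time, lat, lon = time[keep], lat[keep], lon[keep]
        if speed is not None:
            speed = speed[keep]
        if accuracy is not None:
            accuracy = accuracy[keep]

    return Trace(
        participant_id=participant_id,
        group=group,
        time=time,
        lat=lat,
        lon=lon,
        speed=speed,
        accuracy=accuracy,
        sampling_interval=sampling_interval,
    )


def _read_csv(path: Path):
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty file")
    lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy()
    lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy()
    bad = ~np.isfinite(lat) | ~np.isfinite(lon) | (np.abs(lat) > 90) | (np.abs(lon) > 180)
    if bad.any():
        # +2: one for the header, one for 1-based line numbering
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: malformed coordinate at line {line}")
    try:
        time = _parse_times(df["timestamp_iso8601"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    speed = accuracy = None
    if "speed_mps" in df.columns:
        speed = pd.to_numeric(df["speed_mps"], errors="coerce").to_numpy()
    if "accuracy_pct" in df.columns:
        accuracy = pd.to_numeric(df["accuracy_pct"], errors="coerce").to_numpy()
    return time, lat, lon, speed, accuracy


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx(path: Path):
    root = ET.parse(path).getroot()
    lats, lons, times = [], [], []
    for i, pt in enumerate(root.iter(f"{_GPX_NS}trkpt")):
        try:
            lats.append(float(pt.get("lat")))
            lons.append(float(pt.get("lon")))
            t = pt.find(f"{_GPX_NS}time")
            times.append(pd.Timestamp(t.text).timestamp())
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed trkpt #{i}") from exc
    if not times:
        raise ValueError(f"{path}: no track points")
    return np.asarray(times), np.asarray(lats), np.asarray(lons)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace in the CSV dialect, preserving coordinates to 1e-10 deg."""
    ts = pd.to_datetime((trace.time * 1e9).round().astype("int64"), utc=True)
    df = pd.DataFrame(
        {
            "participant_id": trace.participant_id,
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00"),
            "lat": [f"{v:.10f}" for v in trace.lat],
            "lon": [f"{v:.10f}" for v in trace.lon],
            "speed_mps": trace.speed if trace.speed is not None else "",
            "accuracy_pct": trace.accuracy if trace.accuracy is not None else "",
        }
    )
    df.to_csv(path, index=False)


def project_to_plane(trace: Trace) -> Trace:
    """Fill ``trace.xy`` with local azimuthal-equidistant coordinates.

    The projection is centred on the participant's median latitude and
    longitude, with x pointing east and y north at the centre.  Radial
    distances from the centre are exact on the sphere and pairwise
    Euclidean distances agree with geodesics to much better than 0.1%
    over the city-scale spans expected here (tens of km) — a plain
    equirectangular map with a fixed cos(lat0) scale cannot reach that
    at mid latitudes, where the metres-per-degree-longitude factor
    changes by ~0.2% per 10 km travelled north.
    """
    if len(trace) == 0:
        raise ValueError("cannot project an empty trace")
    lat0 = math.radians(float(np.median(trace.lat)))
    lon0 = math.radians(float(np.median(trace.lon)))
    lat = np.radians(trace.lat)
    dlon = np.radians(trace.lon) - lon0
    cos_c = math.sin(lat0) * np.sin(lat) + math.cos(lat0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_M * k * (
        math.cos(lat0) * np.sin(lat) - math.sin(lat0) * np.cos(lat) * np.cos(dlon)
    )
    return replace(
        trace,
        xy=np.column_stack([x, y]),
        projection_origin=(math.degrees(lat0), math.degrees(lon0)),
    )


def split_bouts(trace: Trace, gap_threshold: float = 60.0) -> list[Bout]:
    """Split a trace into maximal runs with inter-sample gaps <= threshold.

    The returned bouts partition the sample index range: every sample
    belongs to exactly one bout.
    """
    n = len(trace)
    if n == 0:
        return []
    gaps = np.diff(trace.time)
    breaks = np.flatnonzero(gaps > gap_threshold) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    return [
        Bout(trace.participant_id, int(s), int(e)) for s, e in zip(starts, ends)
    ]


def label_companionship(
    trace: Trace, annotations: list[OutingAnnotation]
) -> np.ndarray:
    """Label each sample alone/accompanied/unknown by diary-interval containment."""
    labels = np.full(len(trace), UNKNOWN, dtype=object)
    for ann in annotations:
        if ann.participant_id != trace.participant_id:
            raise ValueError(
                f"annotation for {ann.participant_id} applied to {trace.participant_id}"
            )
        inside = (trace.time >= ann.start) & (trace.time < ann.end)
        labels[inside] = ann.companionship
    return labels


def majority_companionship(labels: np.ndarray) -> str:
    """Collapse per-sample labels to one label by majority.

    Returns ``unknown`` when more than half the samples are unlabelled.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        return UNKNOWN
    n_alone = int((labels == ALONE).sum())
    n_acc = int((labels == ACCOMPANIED).sum())
    if (n - n_alone - n_acc) * 2 > n:
        return UNKNOWN
    if n_alone == n_acc:
        return UNKNOWN
    return ALONE if n_alone > n_acc else ACCOMPANIED


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read the ``participant_id,group`` metadata CSV into a dict."""
    df = pd.read_csv(path, dtype=str)
    if not {"participant_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: need participant_id and group columns")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        if row["group"] not in GROUPS:
            raise ValueError(f"{path}: bad group {row['group']!r}")
        out[row["participant_id"]] = row["group"]
    return out


def read_annotations(path: str | Path) -> dict[str, list[OutingAnnotation]]:
    """Read the diary CSV into per-participant annotation lists."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    out: dict[str, list[OutingAnnotation]] = {}
    for _, row in df.iterrows():
        ann = OutingAnnotation(
            participant_id=row["participant_id"],
            start=float(_parse_times(pd.Series([row["start_iso8601"]]))[0]),
            end=float(_parse_times(pd.Series([row["end_iso8601"]]))[0]),
            companionship=row["companionship"],
        )
        out.setdefault(ann.participant_id, []).append(ann)
    for anns in out.values():
        anns.sort(key=lambda a: a.start)
        for a, b in zip(anns, anns[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping annotations for {a.participant_id}"
                )
    return out
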