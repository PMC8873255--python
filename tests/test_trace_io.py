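"""Trace parsing, projection and bout splitting."""

import numpy as np
import pytest
from conftest import haversine_m

from navtrace import (
    OutingAnnotation,
    Trace,
    label_companionship,
    project_to_plane,
    read_annotations,
    read_metadata,
    read_trace,
    split_bouts,
    write_trace,
)
from navtrace.io import majority_companionship


def _make_trace(n=20, seed=0):
    rng = np.random.default_rng(seed)
    t0 = 1.55e9
    return Trace(
        participant_id="A01",
        group="control",
        time=t0 + np.arange(n) * 3.0,
        lat=52.0 + rng.uniform(-0.01, 0.01, n),
        lon=0.1 + rng.uniform(-0.01, 0.01, n),
    )


class TestReadWrite:
    def test_round_trip_preserves_coordinates_and_times(self, tmp_path):
        trace = _make_trace(50)
        path = tmp_path / "t.csv"
        write_trace(trace, path)
        back = read_trace(path, "A01", "control")
        assert np.allclose(back.lat, trace.lat, atol=1e-9)
        assert np.allclose(back.lon, trace.lon, atol=1e-9)
        assert np.allclose(back.time, trace.time, atol=1e-5)

    def test_rows_out_of_order_are_sorted_and_duplicates_dropped(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "participant_id,timestamp_iso8601,lat,lon,speed_mps,accuracy_pct\n"
            "A01,2019-03-04T09:00:06+00:00,52.0,0.1,,\n"
            "A01,2019-03-04T09:00:00+00:00,52.1,0.1,,\n"
            "A01,2019-03-04T09:00:00+00:00,52.2,0.1,,\n"
            "A01,2019-03-04T09:00:03+00:00,52.3,0.1,,\n"
        )
        trace = read_trace(path, "A01", "control")
        assert len(trace) == 3
        assert np.all(np.diff(trace.time) > 0)
        assert trace.lat[0] == 52.1  # first occurrence kept

    def test_malformed_latitude_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,timestamp_iso8601,lat,lon,speed_mps,accuracy_pct\n"
            "A01,2019-03-04T09:00:00+00:00,52.0,0.1,,\n"
            "A01,2019-03-04T09:00:03+00:00,91.2,0.1,,\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_trace(path, "A01", "control")

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "participant_id,timestamp_iso8601,lat,lon,speed_mps,accuracy_pct\n"
        )
        with pytest.raises(ValueError):
            read_trace(path, "A01", "control")

    def test_gpx_track_is_read(self, tmp_path):
        path = tmp_path / "t.gpx"
        path.write_text(
            '<?xml version="1.0"?>\n'
            '<gpx version="1.1" xmlns="http://www.topografix.com/GPX/1/1">'
            "<trk><trkseg>"
            '<trkpt lat="52.0" lon="0.1"><time>2019-03-04T09:00:00Z</time></trkpt>'
            '<trkpt lat="52.001" lon="0.1"><time>2019-03-04T09:00:03Z</time></trkpt>'
            "</trkseg></trk></gpx>"
        )
        trace = read_trace(path, "A01", "patient")
        assert len(trace) == 2 and trace.lat[1] == 52.001


class TestProjection:
    def test_projection_centre_maps_to_origin(self):
        trace = Trace(
            participant_id="A01", group="control",
            time=np.arange(3.0), lat=np.full(3, 52.0), lon=np.full(3, 0.1),
        )
        proj = project_to_plane(trace)
        assert np.allclose(proj.xy, 0.0, atol=1e-9)

    def test_small_latitude_offset_matches_haversine(self):
        trace = Trace(
            participant_id="A01", group="control",
            time=np.arange(2.0), lat=np.array([52.0, 52.001]), lon=np.array([0.1, 0.1]),
        )
        proj = project_to_plane(trace)
        d = np.hypot(*(proj.xy[1] - proj.xy[0]))
        ref = haversine_m(52.0, 0.1, 52.001, 0.1)
        assert abs(d - ref) / ref < 1e-3
        assert abs(d - 111.19) < 0.2

    def test_identical_samples_share_identical_xy(self):
        trace = Trace(
            participant_id="A01", group="control",
            time=np.arange(4.0), lat=np.full(4, 51.5), lon=np.full(4, -0.3),
        )
        proj = project_to_plane(trace)
        assert np.all(proj.xy == proj.xy[0])

    def test_planar_distance_tracks_geodesic_within_point_one_percent(self):
        rng = np.random.default_rng(42)
        lat0, lon0 = 52.0, 0.1
        # points within ~50 km of the centre
        lats = lat0 + rng.uniform(-0.22, 0.22, (1000, 2))
        lons = lon0 + rng.uniform(-0.36, 0.36, (1000, 2))
        trace = Trace(
            participant_id="A01", group="control",
            time=np.arange(2000.0),
            lat=np.concatenate([lats[:, 0], lats[:, 1]]),
            lon=np.concatenate([lons[:, 0], lons[:, 1]]),
        )
        proj = project_to_plane(trace)
        xy1, xy2 = proj.xy[:1000], proj.xy[1000:]
        planar = np.hypot(*(xy2 - xy1).T)
        for k in range(1000):
            ref = haversine_m(lats[k, 0], lons[k, 0], lats[k, 1], lons[k, 1])
            if ref > 1.0:
                assert abs(planar[k] - ref) / ref < 1e-3


class TestBouts:
    def test_uniform_sampling_gives_one_bout(self):
        trace = project_to_plane(_make_trace(100))
        bouts = split_bouts(trace, gap_threshold=60.0)
        assert len(bouts) == 1 and len(bouts[0]) == 100

    def test_long_gap_splits_into_two_bouts(self):
        trace = _make_trace(40)
        trace.time[20:] += 7200.0
        bouts = split_bouts(trace, gap_threshold=60.0)
        assert [(b.start, b.end) for b in bouts] == [(0, 20), (20, 40)]

    def test_single_sample_trace_is_one_bout(self):
        trace = _make_trace(1)
        bouts = split_bouts(trace)
        assert len(bouts) == 1 and len(bouts[0]) == 1

    def test_bouts_partition_every_sample(self):
        rng = np.random.default_rng(3)
        trace = _make_trace(300)
        trace.time = 1.55e9 + np.cumsum(rng.choice([3.0, 5.0, 600.0], 300, p=[0.6, 0.3, 0.1]))
        bouts = split_bouts(trace, gap_threshold=60.0)
        covered = sorted(i for b in bouts for i in range(b.start, b.end))
        assert covered == list(range(300))


class TestCompanionship:
    def test_interval_containment_labels_samples(self):
        trace = _make_trace(30)
        anns = [OutingAnnotation("A01", trace.time[0], trace.time[-1] + 1, "alone")]
        labels = label_companionship(trace, anns)
        assert set(labels) == {"alone"}

    def test_without_annotations_everything_is_unknown(self):
        trace = _make_trace(10)
        assert set(label_companionship(trace, [])) == {"unknown"}

    def test_majority_rule_on_sixty_percent_coverage(self):
        labels = np.array(["alone"] * 6 + ["accompanied"] * 4, dtype=object)
        assert majority_companionship(labels) == "alone"
        labels = np.array(["alone"] * 4 + ["unknown"] * 6, dtype=object)
        assert majority_companionship(labels) == "unknown"


def test_metadata_and_annotation_files(tmp_path):
    (tmp_path / "metadata.csv").write_text(
        "participant_id,group\nA01,control\nB01,patient\n"
    )
    meta = read_metadata(tmp_path / "metadata.csv")
    assert meta == {"A01": "control", "B01": "patient"}
    (tmp_path / "ann.csv").write_text(
        "participant_id,start_iso8601,end_iso8601,companionship\n"
        "B01,2019-03-04T09:00:00+00:00,2019-03-04T09:30:00+00:00,alone\n"
        "B01,2019-03-04T11:00:00+00:00,2019-03-04T11:20:00+00:00,accompanied\n"
    )
    anns = read_annotations(tmp_path / "ann.csv")
    assert len(anns["B01"]) == 2
    (tmp_path / "overlap.csv").write_text(
        "participant_id,start_iso8601,end_iso8601,companionship\n"
        "B01,2019-03-04T09:00:00+00:00,2019-03-04T09:30:00+00:00,alone\n"
        "B01,2019-03-04T09:10:00+00:00,2019-03-04T09:40:00+00:00,accompanied\n"
    )
    with pytest.raises(ValueError, match="overlap"):
        read_annotations(tmp_path / "overlap.csv")
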