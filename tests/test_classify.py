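"""Contact detection, three-segment partition and rM labelling."""

import numpy as np
import pytest

from rmtrack import (
    SimulationParams,
    SpheroidGeometry,
    Track,
    TrackSet,
    align_to_spheroid,
    classify_reverse_migrated,
    cohort_segment_metrics,
    contact_frames,
    segment_track,
    simulate_trackset,
)
from rmtrack.errors import AlignmentError, ParameterError


def radial_track(radii, cell_id="t"):
    """An aligned track running along +x at the given radial distances."""
    radii = np.asarray(radii, dtype=float)
    t = Track(cell_id, frames=np.arange(len(radii)), x=radii,
              y=np.zeros(len(radii)))
    return align_to_spheroid(t, SpheroidGeometry(0.0, 0.0, 1.0))


WORKED = [15.0, 12.0, 9.0, 8.0, 11.0, 14.0]


class TestContactFrames:
    def test_direct_inequality(self):
        assert list(contact_frames(radial_track(WORKED), 10.0)) == [2, 3]

    def test_boundary_point_counts_as_contact(self):
        assert list(contact_frames(radial_track([12.0, 10.0, 15.0]), 10.0)) == [1]

    def test_no_contact_gives_empty(self):
        assert contact_frames(radial_track([11.0, 12.0]), 10.0).size == 0

    def test_unaligned_track_rejected(self):
        raw = Track("t", frames=[0, 1], x=[0.0, 1.0], y=[0.0, 0.0])
        with pytest.raises(AlignmentError):
            contact_frames(raw, 10.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            contact_frames(radial_track(WORKED), 0.0)


class TestSegmentTrack:
    def test_worked_partition(self):
        seg = segment_track(radial_track(WORKED), 10.0)
        assert list(seg.indices("approach")) == [0, 1]
        assert list(seg.indices("within")) == [2, 3]
        assert list(seg.indices("reverse")) == [4, 5]
        assert seg.contacted and seg.rm_label

    def test_excursion_absorbed_into_within(self):
        seg = segment_track(radial_track([15.0, 9.0, 12.0, 9.0, 14.0]), 10.0)
        assert list(seg.indices("within")) == [1, 2, 3]
        assert list(seg.indices("reverse")) == [4]

    def test_never_contacting_track_is_all_approach(self):
        seg = segment_track(radial_track([15.0, 14.0, 13.0]), 10.0)
        assert list(seg.indices("approach")) == [0, 1, 2]
        assert not seg.contacted and not seg.rm_label
        assert seg.n_points("within") == 0 and seg.n_points("reverse") == 0

    def test_track_starting_inside_has_empty_approach_and_can_be_rm(self):
        seg = segment_track(radial_track([5.0, 8.0, 12.0, 20.0]), 10.0)
        assert seg.n_points("approach") == 0
        assert list(seg.indices("within")) == [0, 1]
        assert seg.rm_label

    def test_track_ending_inside_is_not_rm(self):
        seg = segment_track(radial_track([15.0, 9.0, 8.0]), 10.0)
        assert seg.contacted and not seg.rm_label
        assert seg.n_points("reverse") == 0

    def test_single_reverse_point_insufficient_for_rm(self):
        seg = segment_track(radial_track([15.0, 9.0, 14.0]), 10.0)
        assert seg.n_points("reverse") == 1 and not seg.rm_label

    def test_partition_is_exhaustive_and_ordered_on_simulated_cohort(
        self, default_cohort
    ):
        params, ts, _ = default_cohort
        for t in ts.tracks:
            at = align_to_spheroid(t, params.spheroid)
            seg = segment_track(at, params.spheroid.radius)
            a, w, r = seg.approach, seg.within, seg.reverse
            assert a[0] == 0 and r[1] == len(t)
            assert a[1] == w[0] and w[1] == r[0]  # contiguous, ordered
            if not seg.contacted:
                assert a == (0, len(t))


class TestClassifier:
    def test_min_reverse_displacement_monotonically_shrinks_rm_set(
        self, default_cohort
    ):
        params, ts, _ = default_cohort
        previous = None
        for thr in (0.0, 10.0, 50.0, 200.0, 1e6):
            rm = {c for c, v in classify_reverse_migrated(
                ts, params.spheroid, thr).items() if v}
            if previous is not None:
                assert rm <= previous
            previous = rm
        assert previous == set()  # nothing travels 1e6 µm

    def test_growing_radius_weakly_grows_contacted_set(self, default_cohort):
        params, ts, _ = default_cohort
        previous = None
        for radius in (10.0, 30.0, 50.0, 120.0):
            sp = SpheroidGeometry(0.0, 0.0, radius)
            contacted = set()
            for t in ts.tracks:
                if segment_track(align_to_spheroid(t, sp), radius).contacted:
                    contacted.add(t.cell_id)
            if previous is not None:
                assert previous <= contacted
            previous = contacted

    def test_two_point_cells_handled_without_abort(self, spheroid):
        stub = Track("stub", frames=[0], x=[100.0], y=[0.0])
        ok = Track("ok", frames=np.arange(3), x=[60.0, 40.0, 60.0], y=[0.0] * 3)
        ts = TrackSet(tracks=[stub, ok], frame_interval=1.0)
        labels = classify_reverse_migrated(ts, spheroid)
        assert labels == {"stub": False, "ok": False}  # 1-pt reverse seg

    def test_labels_recover_ground_truth_on_clean_geometry(self):
        params = SimulationParams(n_cells=80, n_frames=220, p_rm=0.5, seed=11)
        ts, gt = simulate_trackset(params)
        labels = classify_reverse_migrated(ts, params.spheroid)
        assert labels == gt.rm_labels()


class TestCohortMetrics:
    def test_no_reverse_rows_when_nothing_reverses(self):
        params = SimulationParams(n_cells=20, p_rm=0.0, seed=3)
        ts, _ = simulate_trackset(params)
        df = cohort_segment_metrics(ts)
        assert (df["segment"] == "reverse").sum() == 0
        assert not df["rm_label"].any()

    def test_rows_match_bruteforce_recomputation(self, default_cohort):
        params, ts, _ = default_cohort
        df = cohort_segment_metrics(ts)
        radius = params.spheroid.radius
        for _, row in df.sample(40, random_state=0).iterrows():
            t = ts.get(row["cell_id"])
            x = t.x - params.spheroid.center_x
            y = t.y - params.spheroid.center_y
            r = np.hypot(x, y)
            inside = np.flatnonzero(r <= radius)
            if row["segment"] == "whole":
                lo, hi = 0, len(t)
            elif row["segment"] == "approach":
                lo, hi = 0, inside[0] if inside.size else len(t)
            elif row["segment"] == "within":
                lo, hi = inside[0], inside[-1] + 1
            else:
                lo, hi = inside[-1] + 1, len(t)
            d = np.sqrt(np.diff(x[lo:hi]) ** 2 + np.diff(y[lo:hi]) ** 2)
            d_total = d.sum()
            disp = np.hypot(x[hi - 1] - x[lo], y[hi - 1] - y[lo])
            assert row["d_total"] == pytest.approx(d_total, rel=1e-9)
            assert row["disp"] == pytest.approx(disp, rel=1e-9, abs=1e-9)
            if d_total > 0:
                assert row["straightness"] == pytest.approx(disp / d_total, rel=1e-9)

    def test_noiseless_cohort_has_exact_kinematics(self):
        params = SimulationParams(
            n_cells=10, n_frames=120, heading_noise_sd=0.0, speed_sd=0.0,
            persistence=0.0, p_rm=1.0, dwell_frames_mean=3.0, seed=5,
        )
        ts, _ = simulate_trackset(params)
        df = cohort_segment_metrics(ts)
        approach = df[df["segment"] == "approach"]
        np.testing.assert_allclose(approach["straightness"], 1.0, atol=1e-12)
        within = df[df["segment"] == "within"]
        np.testing.assert_allclose(
            within["mean_velocity"],
            params.within_speed_factor * params.speed_mean,
            rtol=1e-12,
        )
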