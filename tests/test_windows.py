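"""Sliding-window law, the PAFN extraction protocol, dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafnet import synthetic, windows
from pafnet.containers import RRSequence
from pafnet.windows import (SelectionPolicy, WindowConfig, build_dataset,
                            select_pafn_segments, slide)


def uniform_rr(n: int, rr: float = 0.8, record_id: str = "u") -> RRSequence:
    return RRSequence(intervals=np.full(n, rr), record_id=record_id)


def brute_force_starts(m: int, n: int, step: int) -> list[int]:
    """Enumeration oracle: every start whose window fits."""
    return [k for k in range(0, m + 1) if k % step == 0 and k + n <= m]


class TestSlide:
    def test_step_one_window_count(self):
        out = slide(uniform_rr(5), WindowConfig(N=3, step=1))
        assert len(out) == 3

    def test_window_equals_whole_sequence_when_m_equals_n(self):
        rr = uniform_rr(7)
        out = slide(rr, WindowConfig(N=7))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].values, rr.intervals)

    def test_larger_step(self):
        out = slide(uniform_rr(10), WindowConfig(N=3, step=4))
        assert len(out) == 2  # starts 0 and 4; start 8 would overrun

    def test_short_sequence_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = slide(uniform_rr(5), WindowConfig(N=10))
        assert out == []
        assert "skipped" in caplog.text

    def test_window_end_times_track_last_beat(self, nsr_rr):
        cfg = WindowConfig(N=50, step=1)
        out = slide(nsr_rr, cfg)
        for k in (0, 100, len(out) - 1):
            assert out[k].end_time == pytest.approx(nsr_rr.beat_times[k + cfg.N - 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(m=st.integers(2, 300), n=st.integers(2, 300), step=st.integers(1, 10))
    def test_window_count_matches_enumeration_oracle(self, m, n, step):
        out = slide(uniform_rr(m), WindowConfig(N=n, step=step))
        assert len(out) == len(brute_force_starts(m, n, step))


def rr_covering(duration_s: float, rr: float = 0.8, record_id: str = "cov") -> RRSequence:
    n = int(duration_s / rr) - 1
    return RRSequence(intervals=np.full(n, rr), record_id=record_id)


class TestSelectPafn:
    def test_guard_zone_around_qualifying_episode(self):
        track = synthetic.generate_rhythm_track([(10_000.0, 11_000.0)], 14_400.0)
        rr = rr_covering(14_400.0)
        slices = select_pafn_segments(track, rr)
        assert slices, "at least the (0, 1800) slice must survive"
        for sl in slices:
            assert sl.end_time <= 7300.0 or sl.start_time >= 13_700.0
        assert (slices[0].start_time, slices[0].end_time) == (0.0, 1800.0)

    def test_all_normal_record_fully_eligible(self):
        track = synthetic.generate_rhythm_track(None, 3 * 1800.0)
        slices = select_pafn_segments(track, rr_covering(3 * 1800.0))
        assert len(slices) == 3
        assert [s.start_time for s in slices] == [0.0, 1800.0, 3600.0]

    def test_short_af_excluded_but_no_guard_zone(self):
        # a 200 s AF span is not an "episode": time right next to it stays
        # eligible, but the span itself never lands inside a slice's content
        track = synthetic.generate_rhythm_track([(2000.0, 2200.0)], 7200.0)
        rr = rr_covering(7200.0)
        slices = select_pafn_segments(track, rr)
        assert slices
        for sl in slices:
            assert not (sl.start_time < 2200.0 and sl.end_time > 2000.0)
        covered = sum(sl.end_time - sl.start_time for sl in slices)
        assert covered >= 2 * 1800.0  # eligibility not wiped out by the guard rule

    def test_flutter_and_junctional_content_excluded(self):
        track = synthetic.generate_rhythm_track(
            None, 7200.0, extra_labels=[(1000.0, 1500.0, "AFL"), (4000.0, 4100.0, "J")])
        for sl in select_pafn_segments(track, rr_covering(7200.0)):
            for a, b in ((1000.0, 1500.0), (4000.0, 4100.0)):
                assert not (sl.start_time < b and sl.end_time > a)

    def test_no_eligible_slice_returns_empty(self):
        track = synthetic.generate_rhythm_track([(0.0, 400.0)], 1000.0)
        assert select_pafn_segments(track, rr_covering(1000.0)) == []

    def test_next_onset_recorded_for_upstream_slices(self):
        track = synthetic.generate_rhythm_track([(10_000.0, 11_000.0)], 14_400.0)
        slices = select_pafn_segments(track, rr_covering(14_400.0))
        pre = [s for s in slices if s.end_time <= 10_000.0]
        assert pre and all(s.next_onset_time == 10_000.0 for s in pre)


class TestBuildDataset:
    def test_preselected_records_window_count_formula(self):
        n_rec, m, N = 5, 1500, 100
        paf = [(uniform_rr(m, record_id=f"p{i}"), None) for i in range(n_rec)]
        ds = build_dataset(paf, [], WindowConfig(N=N))
        assert len(ds) == n_rec * (m - N + 1) == 5 * 1401
        assert ds.class_counts == {"PAFN": 5 * 1401, "N": 0}

    def test_normal_only_dataset_reports_zero_pafn(self):
        ds = build_dataset([], [uniform_rr(300)], WindowConfig(N=100))
        assert ds.class_counts["PAFN"] == 0
        assert ds.class_counts["N"] == 201

    def test_count_additivity_over_mixed_records(self):
        N = 50
        paf = [(uniform_rr(m, record_id=f"p{m}"), None) for m in (120, 333)]
        nsr = [uniform_rr(m, record_id=f"n{m}") for m in (80, 500)]
        ds = build_dataset(paf, nsr, WindowConfig(N=N))
        expect = sum(m - N + 1 for m in (120, 333, 80, 500))
        assert len(ds) == expect

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            build_dataset([], [], WindowConfig(N=10))

    def test_pafn_windows_respect_45_min_guard(self):
        track = synthetic.generate_rhythm_track([(9000.0, 9600.0)], 14_400.0)
        rr = rr_covering(14_400.0)
        ds = build_dataset([(rr, track)], [], WindowConfig(N=100),
                           SelectionPolicy())
        tto = ds.meta.loc[ds.y == 1, "time_to_onset"].dropna()
        assert len(tto) and (tto >= 45 * 60).all()

    def test_no_window_crosses_record_boundary(self):
        ds = build_dataset([(uniform_rr(120, record_id="a"), None)],
                           [uniform_rr(120, record_id="b")], WindowConfig(N=100))
        assert (ds.meta.groupby("record_id").size() == 21).all()

    def test_save_load_round_trip(self, tmp_path, tiny_dataset):
        p = tmp_path / "ds.npz"
        tiny_dataset.save(p)
        back = windows.WindowDataset.load(p)
        np.testing.assert_array_equal(back.X, tiny_dataset.X)
        np.testing.assert_array_equal(back.y, tiny_dataset.y)
        assert list(back.meta["record_id"]) == list(tiny_dataset.meta["record_id"])
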