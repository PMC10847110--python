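"""Bout detection, the sub-minute grouping rule (with its brute-force
oracle), and running exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitcontext.segmentation import (
    SteppingBout,
    WalkingPeriod,
    attach_strides,
    detect_bouts,
    exclude_running,
    group_bouts,
    ingest_bouts,
)
from gaitcontext.signals import AccelerometerRecording, StrideSequence


def _bouts(*intervals):
    return [SteppingBout(s, e) for s, e in intervals]


def split_oracle(intervals, gap_max):
    """Independent grouping oracle: recursively split the bout list at the
    largest gap that reaches the threshold."""
    if not intervals:
        return []
    gaps = [intervals[i + 1][0] - intervals[i][1]
            for i in range(len(intervals) - 1)]
    if not gaps or max(gaps) < gap_max:
        return [intervals]
    k = int(np.argmax(gaps))
    return split_oracle(intervals[:k + 1], gap_max) + \
        split_oracle(intervals[k + 1:], gap_max)


class TestGroupBouts:
    def test_gap_59s_merges(self):
        periods = group_bouts(_bouts((0, 60), (119, 180)))
        assert len(periods) == 1
        assert periods[0].start_s == 0 and periods[0].end_s == 180
        assert periods[0].standing_time_s == pytest.approx(59.0)

    def test_gap_61s_splits(self):
        periods = group_bouts(_bouts((0, 60), (121, 180)))
        assert len(periods) == 2

    def test_gap_exactly_60s_splits(self):
        """The rule is strictly less-than one minute."""
        periods = group_bouts(_bouts((0, 60), (120, 180)))
        assert len(periods) == 2

    def test_single_bout_period(self):
        periods = group_bouts(_bouts((0, 120)))
        assert len(periods) == 1
        assert periods[0].standing_time_s == 0.0

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError):
            group_bouts(_bouts((0, 60), (50, 90)))

    def test_non_standing_gap_always_splits(self):
        # gap [60, 99] only partially covered by standing -> split
        periods = group_bouts(_bouts((0, 60), (99, 150)),
                              standing_intervals=[(60.0, 80.0)])
        assert len(periods) == 2
        # fully covered -> merge
        periods = group_bouts(_bouts((0, 60), (99, 150)),
                              standing_intervals=[(60.0, 99.0)])
        assert len(periods) == 1

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 5000), st.floats(1, 300)),
                    min_size=1, max_size=25))
    def test_matches_recursive_split_oracle(self, raw):
        starts = sorted(s for s, _ in raw)
        intervals = []
        t = 0.0
        for (s, d) in zip(starts, (d for _, d in raw)):
            a = max(s, t + 1e-3)
            intervals.append((a, a + d))
            t = a + d
        got = group_bouts(_bouts(*intervals))
        want = split_oracle(intervals, 60.0)
        assert [len(p.bouts) for p in got] == [len(g) for g in want]
        assert [p.start_s for p in got] == [g[0][0] for g in want]

    def test_idempotent_on_grouped_output(self):
        periods = group_bouts(_bouts((0, 30), (50, 80), (200, 230)))
        again = group_bouts([b for p in periods for b in p.bouts])
        assert [(p.start_s, p.end_s) for p in again] == \
            [(p.start_s, p.end_s) for p in periods]

    def test_every_bout_in_exactly_one_period(self):
        bouts = _bouts((0, 10), (30, 40), (200, 210), (400, 410))
        periods = group_bouts(bouts)
        assigned = [b for p in periods for b in p.bouts]
        assert assigned == bouts


class TestDetectBouts:
    def test_boundaries_close_to_truth(self, small_cohort):
        pid = small_cohort.participants[0].participant_id
        rec = small_cohort.recording(pid)
        detected = detect_bouts(rec)
        true_bouts = [b for per in small_cohort.schedules[pid]
                      for b in per.bouts]
        jaccards = []
        for tb in true_bouts:
            overlaps = [(min(tb[1], b.end_s) - max(tb[0], b.start_s), b)
                        for b in detected]
            ov, best = max(overlaps, key=lambda x: x[0])
            assert ov > 0, f"true bout {tb} undetected"
            assert abs(best.start_s - tb[0]) <= 1.0
            assert abs(best.end_s - tb[1]) <= 1.0
            union = max(tb[1], best.end_s) - min(tb[0], best.start_s)
            jaccards.append(ov / union)
        assert np.mean(jaccards) >= 0.9

    def test_all_standing_recording_empty(self):
        rng = np.random.default_rng(0)
        samples = np.array([0.1, 0.0, 0.99]) + rng.normal(0, 0.05, (2400, 3))
        rec = AccelerometerRecording("T", 20.0, samples)
        assert detect_bouts(rec) == []

    def test_empty_recording_empty(self):
        rec = AccelerometerRecording("T", 20.0, np.empty((0, 3)))
        assert detect_bouts(rec) == []

    def test_ingest_mode_passthrough(self):
        table = pd.DataFrame(
            {
                "participant_id": ["P", "P", "P"],
                "start_s": [0.0, 70.0, 65.0],
                "end_s": [60.0, 120.0, 70.0],
                "activity": ["stepping", "stepping", "standing"],
            }
        )
        bouts, standing = ingest_bouts(table)
        assert [(b.start_s, b.end_s) for b in bouts] == [(0, 60), (70, 120)]
        assert all(b.source == "ingested" for b in bouts)
        assert standing == [(65.0, 70.0)]


class TestExcludeRunning:
    def _period(self, freq):
        bout = SteppingBout(0.0, 30.0)
        events = np.arange(0.5, 29.5, 1.0 / freq)
        p = WalkingPeriod("P", [bout], strides=StrideSequence(events))
        return p

    def test_walking_cadence_retained(self):
        kept, removed = exclude_running([self._period(0.9)])
        assert len(kept) == 1 and removed == 0

    def test_running_cadence_removed(self):
        kept, removed = exclude_running([self._period(1.5)])
        assert kept == [] and removed == 1

    def test_count_conservation(self):
        periods = [self._period(f) for f in (0.8, 1.5, 1.0, 1.6)]
        kept, removed = exclude_running(periods)
        assert len(kept) + removed == len(periods)
        assert removed == 2


class TestAttachStrides:
    def test_attached_strides_match_truth(self, small_cohort):
        pid = small_cohort.participants[1].participant_id
        rec = small_cohort.recording(pid)
        per = small_cohort.schedules[pid][0]
        wp = group_bouts([SteppingBout(s, e) for s, e in per.bouts],
                         participant_id=pid)
        assert len(wp) == 1
        attach_strides(wp, rec)
        n_true = per.stride_events.size
        assert abs(len(wp[0].strides) - n_true) <= max(3, 0.1 * n_true)
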