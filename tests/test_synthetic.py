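"""Generator checks: calibration to configured distributions, ground-truth
consistency, waveform periodicity, and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gaitcontext.config import (
    CohortConfig,
    ContextProfile,
    default_indoor_profile,
    default_outdoor_profile,
)
from gaitcontext.speed import stride_speed
from gaitcontext.synthetic import (
    ParticipantProfile,
    generate_cohort,
    sample_schedule,
    synthesize_recording,
)


def default_profiles():
    return (default_indoor_profile(), default_outdoor_profile())


class TestSampleSchedule:
    def test_no_interruptions_gives_single_bout(self, participant):
        profiles = tuple(
            dataclasses.replace(p, interruption_rate_per_min=0.0)
            for p in default_profiles()
        )
        cfg = CohortConfig(mixed_fraction=0.0, unlabeled_fraction=0.0)
        periods = sample_schedule(participant, 20, profiles, seed=3, config=cfg)
        for per in periods:
            assert len(per.bouts) == 1
            assert per.standing_time_s == pytest.approx(0.0, abs=1e-9)

    def test_outdoor_duration_mean_matches_configuration(self, participant):
        """Law of large numbers: over 2000 periods the empirical outdoor
        mean duration is within 5% of the configured 11.4 min."""
        cfg = CohortConfig(mixed_fraction=0.0, unlabeled_fraction=0.0)
        part = dataclasses.replace(participant, context_mix=0.0)
        periods = sample_schedule(part, 2000, default_profiles(), seed=11,
                                  config=cfg)
        durations = np.array([p.duration_s / 60.0 for p in periods])
        assert np.all([p.context == "outdoor" for p in periods])
        assert durations.mean() == pytest.approx(11.4, rel=0.05)

    def test_class_conditional_calibration(self, participant):
        """Continuity and stride-speed means also track the configured
        class-conditional values (5% relative)."""
        cfg = CohortConfig(mixed_fraction=0.0, unlabeled_fraction=0.0)
        part = dataclasses.replace(participant, context_mix=0.5)
        periods = sample_schedule(part, 3000, default_profiles(), seed=13,
                                  config=cfg)
        df = pd.DataFrame(
            {
                "context": [p.context for p in periods],
                "duration": [p.duration_s / 60 for p in periods],
                "continuity": [100 * (1 - p.standing_time_s / p.duration_s)
                               for p in periods],
                "speed": [p.stride_speeds.mean() for p in periods],
            }
        )
        means = df.groupby("context").mean()
        assert means.loc["indoor", "duration"] == pytest.approx(2.2, rel=0.05)
        assert means.loc["indoor", "continuity"] == pytest.approx(61.6, rel=0.05)
        assert means.loc["outdoor", "continuity"] == pytest.approx(81.7, rel=0.05)
        assert means.loc["indoor", "speed"] == pytest.approx(1.10, rel=0.05)
        assert means.loc["outdoor", "speed"] == pytest.approx(1.38, rel=0.05)

    def test_degenerate_mixture_all_indoor(self, participant):
        part = dataclasses.replace(participant, context_mix=1.0)
        cfg = CohortConfig(mixed_fraction=0.0, unlabeled_fraction=0.0)
        periods = sample_schedule(part, 50, default_profiles(), seed=5,
                                  config=cfg)
        assert all(p.context == "indoor" for p in periods)

    def test_fixed_seed_reproduces_schedule(self, participant):
        a = sample_schedule(participant, 10, default_profiles(), seed=42)
        b = sample_schedule(participant, 10, default_profiles(), seed=42)
        for pa, pb in zip(a, b):
            assert pa.start_s == pb.start_s and pa.end_s == pb.end_s
            np.testing.assert_array_equal(pa.stride_events, pb.stride_events)

    def test_invalid_arguments(self, participant):
        with pytest.raises(ValueError):
            sample_schedule(participant, 0, default_profiles(), seed=1)
        with pytest.raises(ValueError):
            ParticipantProfile("X", 0.9, 1.3, 1.2, 0.5)  # b >= 1

    def test_ground_truth_invariants(self, participant):
        periods = sample_schedule(participant, 30, default_profiles(), seed=9)
        for per in periods:
            per.validate()
            assert per.standing_time_s < per.duration_s

    def test_speeds_consistent_with_power_law(self, participant):
        """Ground-truth speeds equal the power-law map applied to
        ground-truth frequencies, to 1e-9 relative tolerance."""
        periods = sample_schedule(participant, 20, default_profiles(), seed=17)
        model = participant.speed_model
        for per in periods:
            if per.stride_frequencies.size == 0:
                continue
            np.testing.assert_allclose(
                stride_speed(per.stride_frequencies, model),
                per.stride_speeds, rtol=1e-9)


class TestSynthesizeRecording:
    def test_autocorrelation_peaks_at_stride_period(self, participant):
        from tests.conftest import single_bout_recording
        rec, bout, cfg = single_bout_recording(0.9, duration_s=60.0, seed=2)
        fs = rec.sampling_rate
        seg = rec.slice(*bout).astype(float)
        x = seg[:, 0] - seg[:, 0].mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1:]
        lo, hi = int(0.6 * fs), int(2.0 * fs)
        lag = (lo + int(np.argmax(ac[lo:hi]))) / fs
        assert abs(lag - 1 / 0.9) <= 1.0 / fs + 1e-9

    def test_zero_noise_standing_is_constant_gravity(self, participant):
        from tests.conftest import single_bout_recording
        rec, bout, cfg = single_bout_recording(0.9, seed=2, noise_sd=0.0)
        standing = rec.slice(0.0, bout[0] - 2.0)
        assert np.allclose(standing, standing[0], atol=1e-6)
        assert np.linalg.norm(standing[0]) == pytest.approx(1.0, abs=1e-5)

    def test_same_seed_bit_identical(self, participant):
        periods = sample_schedule(participant, 3, default_profiles(), seed=4)
        r1 = synthesize_recording(periods, participant, 20.0, seed=6)
        r2 = synthesize_recording(periods, participant, 20.0, seed=6)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_empty_schedule_gives_empty_recording(self, participant):
        rec = synthesize_recording([], participant, 20.0, seed=0)
        assert rec.n_samples == 0
        assert rec.sampling_rate == 20.0

    def test_samples_within_sensor_range(self, participant):
        periods = sample_schedule(participant, 2, default_profiles(), seed=8)
        rec = synthesize_recording(periods, participant, 20.0, seed=8)
        assert np.all(np.abs(rec.samples) <= 4.0)


class TestGenerateCohort:
    def test_indoor_fraction_near_80_20(self):
        """Cohort-level label mix: indoor share of the labeled pure periods
        within 3 percentage points of the configured 80%."""
        cohort = generate_cohort(20, 40, seed=31)
        labels = cohort.label_table()["label"]
        pure = labels[labels.isin(["indoor", "outdoor"])]
        assert abs((pure == "indoor").mean() - 0.80) < 0.03

    def test_one_period_per_participant(self):
        cohort = generate_cohort(8, 1, seed=2)
        assert len(cohort.truth_table()) == 8

    def test_same_seed_identical_label_tables(self):
        t1 = generate_cohort(4, 10, seed=9).label_table()
        t2 = generate_cohort(4, 10, seed=9).label_table()
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, 10, seed=0)

    def test_recordings_reproducible(self, small_cohort):
        pid = small_cohort.participants[0].participant_id
        r1 = small_cohort.recording(pid)
        r2 = small_cohort.recording(pid)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_tables_cover_all_periods(self, small_cohort):
        truth = small_cohort.truth_table()
        labels = small_cohort.label_table()
        n = sum(len(v) for v in small_cohort.schedules.values())
        assert len(truth) == n and len(labels) == n
        assert set(labels["label"]) <= {"indoor", "outdoor", "mixed",
                                        "unlabeled"}

    def test_interruption_lengths_below_grouping_threshold(self):
        with pytest.raises(ValueError):
            ContextProfile("indoor", 2.2,
                           interruption_len_s=(5.0, 65.0)).validate()
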