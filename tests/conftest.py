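"""Shared fixtures: small synthetic cohorts and single-bout recordings.

Everything is generated programmatically at fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitcontext.config import CohortConfig
from gaitcontext.synthetic import (
    Cohort,
    ParticipantProfile,
    generate_cohort,
    feature_table_from_truth,
)


@pytest.fixture(scope="session")
def participant() -> ParticipantProfile:
    return ParticipantProfile(
        participant_id="T01", leg_length_m=0.885, speed_param_a=1.3,
        speed_param_b=0.4, context_mix=0.8,
    )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """5 participants x 30 periods, schedule-level work only."""
    return generate_cohort(5, 30, seed=7)


@pytest.fixture(scope="session")
def truth_features(small_cohort):
    return feature_table_from_truth(small_cohort)


@pytest.fixture(scope="session")
def midsize_truth_features():
    """12 participants x 60 periods of ground-truth features, enough for
    classifier protocol checks without any signal processing."""
    cohort = generate_cohort(12, 60, seed=21)
    return cohort, feature_table_from_truth(cohort)


def single_bout_recording(freq_hz: float, duration_s: float = 60.0,
                          seed: int = 0, noise_sd: float | None = None,
                          participant: ParticipantProfile | None = None):
    """A recording containing one constant-frequency walking bout with
    30 s standing margins; returns (recording, bout interval, config)."""
    from gaitcontext.synthetic import PeriodSchedule, synthesize_recording

    part = participant or ParticipantProfile(
        participant_id="T01", leg_length_m=0.885, speed_param_a=1.3,
        speed_param_b=0.4, context_mix=0.8)
    cfg = CohortConfig()
    if noise_sd is not None:
        import dataclasses
        cfg = dataclasses.replace(cfg, noise_sd_g=noise_sd)
    start = 30.0
    events = start + np.arange(int(duration_s * freq_hz) + 1) / freq_hz
    events = events[events <= start + duration_s + 1e-9]
    n = events.size - 1
    period = PeriodSchedule(
        participant_id=part.participant_id, period_id="T01_0000",
        context="indoor", majority_context="indoor", label="indoor",
        start_s=start, end_s=start + duration_s,
        bouts=[(start, start + duration_s)],
        bout_events=[events],
        stride_frequencies=np.full(n, freq_hz),
        stride_speeds=np.full(n, float(freq_hz)),  # placeholder speeds
    )
    rec = synthesize_recording([period], part, cfg.sampling_rate_hz,
                               seed=seed, config=cfg)
    return rec, (start, start + duration_s), cfg
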