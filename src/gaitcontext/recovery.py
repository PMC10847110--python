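"""Full-chain recovery analysis on the default synthetic cohort.

Runs signal synthesis -> bout detection -> period grouping -> stride
detection -> features on the default 20-participant cohort and measures
the class-conditional quantities the generator was calibrated to produce:
mean duration and continuity per context, the mixed-model context effects
on duration and continuity, and the outdoor-indoor stride-speed gap
estimated through the power-law speed model. Classes are taken from the
ground-truth context of each period (mixed periods are excluded), so the
numbers measure the fidelity of the measurement chain, not of the
classifier.
"""

from __future__ import annotations

from .config import RunConfig
from .features import build_feature_table
from .pipeline import estimate_period_speeds, segment_cohort
from .stats import fit_context_model
from .synthetic import generate_cohort


def run_recovery(seed: int, n_participants: int = 20,
                 periods_per_participant: int = 170) -> dict:
    """Measure end-to-end recovery of the generator's class-conditional
    structure; returns the summary quantities plus problem sizes."""
    config = RunConfig(seed=seed)
    config.cohort.n_participants = n_participants
    config.cohort.periods_per_participant = periods_per_participant
    config.validate()

    cohort = generate_cohort(n_participants, periods_per_participant,
                             config.cohort, seed=seed)
    periods, _, _ = segment_cohort(cohort, config)

    # label detected periods with the *true* context of the overlapping
    # scheduled period
    truth = cohort.truth_table()
    truth_labels = truth.drop(columns=["label"]).rename(
        columns={"start_s": "period_start_s", "end_s": "period_end_s",
                 "context": "label"})[
        ["participant_id", "period_start_s", "period_end_s", "label"]]
    participants = cohort.participant_table()
    features = build_feature_table(periods, participants, truth_labels)
    pure = features[features["label"].isin(["indoor", "outdoor"])]

    means = pure.groupby("label")[["duration_min", "continuity_pct"]].mean()

    dur = fit_context_model(pure["duration_min"].to_numpy(),
                            pure["label"].to_numpy(),
                            pure["participant_id"].to_numpy(),
                            outcome_name="duration_min")
    cont = fit_context_model(pure["continuity_pct"].to_numpy(),
                             pure["label"].to_numpy(),
                             pure["participant_id"].to_numpy(),
                             outcome_name="continuity_pct")

    speeds = estimate_period_speeds(periods, participants)
    period_speed = (speeds.groupby("period_id", as_index=False)["speed_ms"]
                    .mean()
                    .merge(pure[["period_id", "label"]], on="period_id"))
    class_speed = period_speed.groupby("label")["speed_ms"].mean()

    return {
        "n_periods": int(len(pure)),
        "n_strides": int(pure["n_strides"].sum()),
        "outdoor_duration_min": float(means.loc["outdoor", "duration_min"]),
        "indoor_duration_min": float(means.loc["indoor", "duration_min"]),
        "outdoor_continuity_pct": float(means.loc["outdoor",
                                                  "continuity_pct"]),
        "indoor_continuity_pct": float(means.loc["indoor", "continuity_pct"]),
        "duration_effect_min": float(dur.estimate),
        "continuity_effect_pct": float(cont.estimate),
        "speed_gap_ms": float(class_speed["outdoor"] - class_speed["indoor"]),
    }
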