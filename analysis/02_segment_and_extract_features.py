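#!/usr/bin/env python
"""Run the measurement chain: waveforms -> bouts -> walking periods ->
biomechanics features -> stride-speed estimates.

Regenerates the cohort from the same seed as 01, synthesizes each
participant's raw recording, detects stepping bouts and strides, groups
bouts into walking periods (standing gaps < 60 s merge), and writes
results/features.csv plus per-stride speed estimates. Prints how well the
detected feature table recovers the generator's class-conditional means.
"""

import argparse
from pathlib import Path

from gaitcontext.config import RunConfig
from gaitcontext.features import build_feature_table
from gaitcontext.pipeline import estimate_period_speeds, segment_cohort
from gaitcontext.synthetic import generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--participants", type=int, default=20)
    ap.add_argument("--periods", type=int, default=170)
    args = ap.parse_args()

    config = RunConfig(seed=args.seed)
    cohort = generate_cohort(args.participants, args.periods, config.cohort,
                             seed=args.seed)
    periods, bout_df, counters = segment_cohort(cohort, config)
    participants = cohort.participant_table()
    features = build_feature_table(periods, participants,
                                   cohort.label_table())
    speeds = estimate_period_speeds(periods, participants)

    args.outdir.mkdir(parents=True, exist_ok=True)
    features.to_csv(args.outdir / "features.csv", index=False)
    speeds.to_csv(args.outdir / "stride_speeds.csv", index=False,
                  float_format="%.6f")
    bout_df.to_csv(args.outdir / "bouts_detected.csv", index=False)
    participants.to_csv(args.outdir / "participants.csv", index=False)

    print(f"segmentation: {counters['n_bouts']} bouts -> "
          f"{counters['n_periods_raw']} periods "
          f"({counters['n_running_excluded']} running-like excluded)")
    print(f"feature table: {len(features)} rows -> "
          f"{args.outdir / 'features.csv'}")
    pure = features[features["label"].isin(["indoor", "outdoor"])]
    print(pure.groupby("label")[["duration_min", "continuity_pct"]]
          .mean().round(3).to_string())


if __name__ == "__main__":
    main()
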