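"""End-to-end orchestration: generate -> detect -> segment -> featurize ->
train/select -> classify -> characterize.

Each stage writes its CSV artifact under the run's output directory and the
run closes with a single JSON report; identical config + seed reproduce the
report byte for byte. Waveforms are synthesized per participant and
discarded after segmentation, keeping memory flat in cohort size.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    classify,
    permutation_importance,
    pure_context_rows,
    select_case,
    select_model,
    train_lopo,
)
from .config import RunConfig, run_config_to_dict
from .features import build_feature_table
from .segmentation import (
    attach_strides,
    detect_bouts,
    exclude_running,
    group_bouts,
    period_frequencies,
)
from .speed import normalize_speed, stride_speed
from .stats import compare_structures, fit_context_model, residual_diagnostics
from .synthetic import Cohort, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and artifact path."""

    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (artifact: {artifact}): {cause}")
        self.stage = stage
        self.artifact = artifact


def segment_cohort(cohort: Cohort, config: RunConfig
                   ) -> tuple[list, pd.DataFrame, dict]:
    """Detect bouts, group them into walking periods, and attach stride
    sequences for every participant. Returns (periods, detected-bout
    table, counters)."""
    seg_cfg = config.segmentation
    all_periods = []
    bout_rows = []
    counters = {"n_bouts": 0, "n_periods_raw": 0, "n_running_excluded": 0}
    for part in cohort.participants:
        rec = cohort.recording(part.participant_id)
        bouts = detect_bouts(rec, seg_cfg)
        counters["n_bouts"] += len(bouts)
        periods = group_bouts(bouts, seg_cfg.gap_max_s,
                              participant_id=part.participant_id)
        attach_strides(periods, rec)
        periods, n_removed = exclude_running(periods, seg_cfg.cadence_max_hz)
        counters["n_periods_raw"] += len(periods) + n_removed
        counters["n_running_excluded"] += n_removed
        all_periods.extend(periods)
        bout_rows.extend(
            (part.participant_id, b.start_s, b.end_s, b.source)
            for b in bouts
        )
    bout_df = pd.DataFrame(bout_rows, columns=["participant_id", "start_s",
                                               "end_s", "source"])
    return all_periods, bout_df, counters


def estimate_period_speeds(periods: list, participants: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per-stride speed estimates from detected stride frequencies via the
    power-law model with each participant's (a, b); one row per stride."""
    from .speed import SpeedModel
    meta = participants.set_index("participant_id")
    rows = []
    for period in periods:
        freqs = period_frequencies(period)
        if freqs.size == 0:
            continue
        rec = meta.loc[period.participant_id]
        model = SpeedModel(float(rec["a"]), float(rec["b"]))
        speeds = stride_speed(freqs, model)
        norm = normalize_speed(speeds, float(rec["leg_length_m"]))
        rows.append(pd.DataFrame({
            "participant_id": period.participant_id,
            "period_id": period.period_id,
            "stride_freq_hz": freqs,
            "speed_ms": speeds,
            "speed_norm": norm,
        }))
    if not rows:
        return pd.DataFrame(columns=["participant_id", "period_id",
                                     "stride_freq_hz", "speed_ms",
                                     "speed_norm"])
    return pd.concat(rows, ignore_index=True)


def characterize(features: pd.DataFrame, speeds: pd.DataFrame,
                 label_column: str = "label") -> dict:
    """Per-class summary block: mean/SD of duration, continuity, and
    stride speed, period and stride counts, and the class mix ratio.

    Class speed is the mean over walking periods of the per-period mean
    stride speed, so every walk counts once; pooling raw strides would
    over-weight long, fast walks (stride count grows with both duration
    and cadence). A missing class yields a partial summary with a warning.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    summary: dict = {"classes": {}, "warnings": []}
    period_speed = (speeds.groupby("period_id", as_index=False)["speed_ms"]
                    .mean()
                    .merge(features[["period_id", label_column]],
                           on="period_id", how="inner"))
    for cls in ("indoor", "outdoor"):
        rows = features[features[label_column] == cls]
        if len(rows) == 0:
            summary["warnings"].append(f"no {cls} periods")
            continue
        cls_speeds = period_speed[period_speed[label_column] == cls]
        summary["classes"][cls] = {
            "n_periods": int(len(rows)),
            "n_strides": int(rows["n_strides"].sum()),
            "duration_min_mean": float(rows["duration_min"].mean()),
            "duration_min_sd": float(rows["duration_min"].std(ddof=1))
            if len(rows) > 1 else 0.0,
            "continuity_pct_mean": float(rows["continuity_pct"].mean()),
            "continuity_pct_sd": float(rows["continuity_pct"].std(ddof=1))
            if len(rows) > 1 else 0.0,
            "speed_ms_mean": float(cls_speeds["speed_ms"].mean())
            if len(cls_speeds) else float("nan"),
            "speed_ms_sd": float(cls_speeds["speed_ms"].std(ddof=1))
            if len(cls_speeds) > 1 else float("nan"),
        }
    n_in = summary["classes"].get("indoor", {}).get("n_periods", 0)
    n_out = summary["classes"].get("outdoor", {}).get("n_periods", 0)
    total = n_in + n_out
    summary["indoor_fraction"] = float(n_in / total) if total else float("nan")
    return summary


def fit_context_models(features: pd.DataFrame, speeds: pd.DataFrame,
                       participants: pd.DataFrame,
                       label_column: str = "label",
                       max_strides_per_period: int = 15,
                       seed: int = 0) -> dict:
    """The three context-comparison mixed models (duration, continuity,
    normalized stride speed), each with residual diagnostics."""
    rows = features[features[label_column].isin(["indoor", "outdoor"])]
    out: dict = {}
    for outcome in ("duration_min", "continuity_pct"):
        res = fit_context_model(
            rows[outcome].to_numpy(), rows[label_column].to_numpy(),
            rows["participant_id"].to_numpy(), outcome_name=outcome)
        diag = residual_diagnostics(
            rows[outcome].to_numpy(), rows[label_column].to_numpy(),
            rows["participant_id"].to_numpy(), res)
        out[outcome] = {"result": res.as_dict(), "diagnostics": diag}

    sp = speeds.merge(rows[["period_id", label_column]], on="period_id",
                      how="inner")
    if len(sp):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        # balanced subsample: at most max_strides_per_period strides per
        # period keeps the nested fit tractable without biasing the means
        sp = sp.iloc[rng.permutation(len(sp))]
        sp = sp[sp.groupby("period_id").cumcount() < max_strides_per_period]
        sp = sp.sort_values(["period_id"], kind="stable").reset_index(drop=True)
        res = fit_context_model(
            sp["speed_norm"].to_numpy(), sp[label_column].to_numpy(),
            sp["participant_id"].to_numpy(),
            period=sp["period_id"].to_numpy(),
            outcome_name="speed_norm")
        diag = residual_diagnostics(
            sp["speed_norm"].to_numpy(), sp[label_column].to_numpy(),
            sp["participant_id"].to_numpy(), res)
        out["speed_norm"] = {"result": res.as_dict(), "diagnostics": diag}
    return out


def _fingerprint(config: RunConfig) -> str:
    data = run_config_to_dict(config)
    data.pop("outdir", None)  # where results land is not part of the science
    payload = json.dumps(data, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report (also written
    as ``report.json`` with CSV artifacts alongside)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_fingerprint": _fingerprint(config),
    }

    stage = "generate"
    try:
        cohort = generate_cohort(config.cohort.n_participants,
                                 config.cohort.periods_per_participant,
                                 config.cohort, seed=config.seed)
        participants = cohort.participant_table()
        participants.to_csv(outdir / "participants.csv", index=False)
        label_table = cohort.label_table()
        label_table.to_csv(outdir / "labels.csv", index=False)
        cohort.truth_table().to_csv(outdir / "ground_truth.csv", index=False)

        stage = "segment"
        periods, bout_df, counters = segment_cohort(cohort, config)
        bout_df.to_csv(outdir / "bouts_detected.csv", index=False)
        if config.cohort.n_participants == 2:
            logger.warning("2-participant cohort: LOPO degenerates to "
                           "1-vs-1 folds")

        stage = "features"
        features = build_feature_table(periods, participants, label_table)
        features.to_csv(outdir / "features.csv", index=False)
        counters["n_feature_rows"] = int(len(features))
        counters["n_short_excluded"] = int(len(periods) - len(features))
        report["counters"] = counters

        stage = "train"
        test_ids = set(participants[participants["is_test"]]["participant_id"])
        pool_feat = features[~features["participant_id"].isin(test_ids)]
        test_feat = features[features["participant_id"].isin(test_ids)]
        bundles = [
            train_lopo(pool_feat, algo, config.classifier, seed=config.seed)
            for algo in ("ensemble_svm", "random_forest")
        ]
        report["cases"] = [b.summary() for b in bundles]
        best_case = select_case(bundles)
        report["selected_case"] = {"algorithm": best_case.algorithm,
                                   "feature_set": best_case.feature_set}
        if len(pure_context_rows(test_feat)) > 0:
            best_fold, test_metrics, test_table = select_model(
                best_case, test_feat, config.classifier)
            test_table.to_csv(outdir / "test_model_metrics.csv", index=False)
            report["test_metrics"] = test_metrics.as_dict()
        else:
            logger.warning("no held-out test participants; choosing the "
                           "fold with the best validation metrics")
            best_fold = min(
                best_case.folds,
                key=lambda f: (-f.metrics.accuracy, -f.metrics.f1,
                               f.held_out))
            report["test_metrics"] = None
        report["selected_model"] = best_fold.held_out

        stage = "importance"
        test_pure = pure_context_rows(test_feat)
        if len(test_pure) < 20:
            logger.warning("test set too small for permutation importance; "
                           "using the training-pool rows")
            test_pure = pure_context_rows(pool_feat)
        imp = permutation_importance(best_fold.model, test_pure,
                                     seed=config.seed)
        imp.to_csv(outdir / "feature_importance.csv", index=False)
        report["feature_importance"] = {
            r.feature: {"mean": float(r.importance_mean),
                        "sd": float(r.importance_sd)}
            for r in imp.itertuples()
        }

        stage = "classify"
        predictions = classify(best_fold.model, features, config.classifier)
        predictions["final_label"] = np.where(
            predictions["label"].isin(["indoor", "outdoor"]),
            predictions["label"], predictions["predicted_label"])
        predictions.to_csv(outdir / "predictions.csv", index=False)

        stage = "characterize"
        speeds = estimate_period_speeds(periods, participants)
        speeds.to_csv(outdir / "stride_speeds.csv", index=False,
                      float_format="%.6f")
        report["characterization"] = characterize(
            predictions, speeds, label_column="final_label")

        stage = "stats"
        report["mixed_models"] = fit_context_models(
            predictions, speeds, participants, label_column="final_label",
            seed=config.seed)
        structure_table = compare_structures(
            predictions["duration_min"].to_numpy()[
                predictions["final_label"].isin(["indoor", "outdoor"])],
            predictions["final_label"][
                predictions["final_label"].isin(["indoor", "outdoor"])
            ].to_numpy(),
            predictions["participant_id"][
                predictions["final_label"].isin(["indoor", "outdoor"])
            ].to_numpy(),
            candidates=("ols", "participant"),
        )
        report["duration_structure_aic"] = structure_table.to_dict("records")
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, str(outdir), exc) from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      allow_nan=True))
    logger.info("run complete: %s", report_path)
    return report
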