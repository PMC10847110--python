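#!/usr/bin/env python
"""Train and select the indoor/outdoor classifier.

Reads results/features.csv and results/participants.csv (from 02), runs
leave-one-participant-out validation of the bagged SVM and random forest
over the 15-participant training pool, picks the best case by average
validation metrics, evaluates its fold models on the 5 held-out test
participants, and quantifies feature importance by permutation on the
test set. Writes the metric tables under results/classification/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gaitcontext.classification import (
    permutation_importance,
    pure_context_rows,
    select_case,
    select_model,
    train_lopo,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--indir", type=Path, default=Path("results"))
    ap.add_argument("--outdir", type=Path,
                    default=Path("results/classification"))
    args = ap.parse_args()

    features = pd.read_csv(args.indir / "features.csv")
    participants = pd.read_csv(args.indir / "participants.csv")
    test_ids = set(participants[participants["is_test"]]["participant_id"])
    pool = features[~features["participant_id"].isin(test_ids)]
    test = features[features["participant_id"].isin(test_ids)]

    bundles = [train_lopo(pool, algo, seed=args.seed)
               for algo in ("ensemble_svm", "random_forest")]
    for b in bundles:
        print(f"{b.algorithm}: avg accuracy {b.avg_accuracy:.3f}, "
              f"F1 {b.avg_f1:.3f}, AUROC {b.avg_auroc:.3f}")
    best = select_case(bundles)
    print(f"selected case: {best.algorithm} ({best.feature_set} features)")

    fold, metrics, per_model = select_model(best, test)
    print(f"best model on the test set: fold {fold.held_out} "
          f"(accuracy {metrics.accuracy:.3f}, F1 {metrics.f1:.3f}, "
          f"AUROC {metrics.auroc if metrics.auroc is None else round(metrics.auroc, 3)})")

    imp = permutation_importance(fold.model, pure_context_rows(test),
                                 seed=args.seed)
    print("permutation importance (accuracy decrease):")
    print(imp.round(4).to_string(index=False))

    args.outdir.mkdir(parents=True, exist_ok=True)
    per_model.to_csv(args.outdir / "test_model_metrics.csv", index=False)
    imp.to_csv(args.outdir / "feature_importance.csv", index=False)
    (args.outdir / "summary.json").write_text(json.dumps({
        "cases": [b.summary() for b in bundles],
        "selected_case": best.algorithm,
        "selected_model": fold.held_out,
        "test_metrics": metrics.as_dict(),
    }, indent=2, sort_keys=True))
    print(f"written to {args.outdir}")


if __name__ == "__main__":
    main()
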