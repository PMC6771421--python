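#!/usr/bin/env python
"""Fit the choice classifiers and rank the decision models.

Cross-validates L1 logistic classifiers (stratified K-fold, one-SEM lambda
rule, MCC scoring) for the single-feature choice models and the two-stage
kinematic-feature + touch-count models, and writes the ranked comparison.
On these sessions choice is generated from whisking midpoint at touch plus
touch count, so the midpoint+count two-stage model should sit at the top
with a negative midpoint weight and positive count weight.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from whiskloc.classifier import (ConfusionMatrix, cross_validate,
                                 fit_two_stage, labels_from, mcc)
from whiskloc.features import FEATURE_SETS

SINGLE_MODELS = ["touch_count", "roll_angle", "whisk_latency", "cue_latency",
                 "radial_distance", "angle"]
TWO_STAGE = ["protraction_midpoint", "angle", "protraction_amplitude",
             "protraction_phase"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--iterations", type=int, default=10)
    args = ap.parse_args()
    table = pd.read_csv(args.results / "features.csv")
    y = labels_from(table, "choice")
    rows = []
    warnings.filterwarnings("ignore", message=".*did not converge.*")

    for name in SINGLE_MODELS:
        predictors = FEATURE_SETS[name]
        sub = table.dropna(subset=predictors)
        res = cross_validate(sub, predictors, "choice",
                             iterations=args.iterations,
                             rng=np.random.default_rng(args.seed))
        rows.append([f"choice {name} (touch trials)", res.mean_mcc, res.sem_mcc,
                     res.mean_accuracy, res.chosen_lambda])

    count_fit = None
    for feat in TWO_STAGE:
        count_fit, touch_fit, pred = fit_two_stage(
            table, feat, "choice", rng=np.random.default_rng(args.seed),
            count_fit=count_fit, iterations=args.iterations)
        m = mcc(ConfusionMatrix.from_predictions(y, pred))
        acc = float(np.mean(pred == y))
        rows.append([f"choice two-stage {feat}+count (all trials)", m,
                     np.nan, acc, touch_fit.chosen_lambda])
        if feat == "protraction_midpoint":
            th = touch_fit.model.theta
            print(f"midpoint+count touch-stage weights: bias {th[0]:+.2f}, "
                  f"midpoint {th[1]:+.2f}, count {th[2]:+.2f}")

    out = pd.DataFrame(rows, columns=["model", "mcc", "sem", "accuracy",
                                      "lambda"])
    out = out.sort_values("mcc", ascending=False, kind="stable")
    out.to_csv(args.results / "model_comparison.csv", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
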