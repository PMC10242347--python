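#!/usr/bin/env python
"""Repeated hold-out comparison of prognostic data types.

Evaluates five data types over shared 70/30 splits — adjacent-normal
expression, tumor expression, the two DEG-ratio feature sets and the
clinical covariates — with a Cox neural network (ridge chosen by threefold
CV per data type) and a clinical Cox model, then compares arms by paired
Wilcoxon tests with BH adjustment.
"""

import argparse
from pathlib import Path

import pandas as pd

from adjnorm.experiments import compare_groups, repeated_holdout
from adjnorm.features import identify_degs, paired_de_fallback, ratio_features
from adjnorm.models import cv_select_hyperparams
from adjnorm.pipeline import DEFAULT_LAMBDA_GRID, default_nn_factory
from adjnorm.preprocess import standardize_matrix
from adjnorm.synth import SimulationConfig, simulate_paired_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-repeats", type=int, default=20)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    study = simulate_paired_study(SimulationConfig(seed=args.seed))
    time, event = study.normal.time, study.normal.event

    de = paired_de_fallback(study.tumor.expression, study.normal.expression)
    degs = identify_degs(de)
    print(f"{len(degs)} DEGs feed the ratio features")

    datasets = {
        "normal": study.normal.expression.to_numpy(),
        "tumor": study.tumor.expression.to_numpy(),
        "ratio_individual": ratio_features(study.tumor.expression, study.normal.expression,
                                           genes=degs, kind="individual").to_numpy(),
        "ratio_median": ratio_features(study.tumor.expression, study.normal.expression,
                                       genes=degs, kind="median").to_numpy(),
        "clinical": study.normal.clinical.to_numpy(),
    }
    grid = [{"lambda_l2": lam} for lam in DEFAULT_LAMBDA_GRID]
    tables = []
    for name, X in datasets.items():
        Z = standardize_matrix(X)[0]
        best, _ = cv_select_hyperparams(default_nn_factory, grid, Z, time, event,
                                        k=3, seed=args.seed + 1009)
        tab = repeated_holdout({name: X}, {"nn": lambda b=best: default_nn_factory(b)},
                               time, event, n_repeats=args.n_repeats, seed=args.seed + 5077)
        tables.append(tab)
        print(f"{name}: lambda={best['lambda_l2']}, mean test C = {tab['c_index'].mean():.3f}")
    eval_table = pd.concat(tables, ignore_index=True)
    eval_table.to_csv(args.out_dir / "eval_table.tsv", sep="\t", index=False)

    comparisons = compare_groups(eval_table, [
        ({"data_type": "normal"}, {"data_type": "tumor"}),
        ({"data_type": "normal"}, {"data_type": "ratio_individual"}),
        ({"data_type": "normal"}, {"data_type": "ratio_median"}),
        ({"data_type": "normal"}, {"data_type": "clinical"}),
        ({"data_type": "ratio_individual"}, {"data_type": "ratio_median"}),
    ])
    comparisons.to_csv(args.out_dir / "comparisons.tsv", sep="\t", index=False)
    print(comparisons[["group_a", "group_b", "mean_a", "mean_b", "p", "p_adj"]].to_string(index=False))
    print("the study plants stronger prognostic signal through normal tissue "
          "(beta 0.6 x 30 genes) than tumor tissue (beta 0.4 x 30): the normal arm "
          "should lead every other data type, and the DEG ratios (DEGs planted "
          "independently of prognosis) should not rescue tumor data")


if __name__ == "__main__":
    main()
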