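#!/usr/bin/env python
"""Clinical Cox baselines, informative-gene density per tissue, and the
correlation between DE fold changes and per-gene Cox coefficients.

Answers three preliminary questions on the simulated discovery cohort:
how prognostic are age and stage alone (C-index, Wald p per covariate);
which tissue carries more genes whose univariate C-index departs from
chance; and whether differential expression predicts prognostic weight.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from adjnorm.experiments import informative_gene_density, lfc_vs_coef_correlation
from adjnorm.features import paired_de_fallback
from adjnorm.preprocess import standardize_genes
from adjnorm.screening import clinical_cox_predictor
from adjnorm.survival import concordance_index, likelihood_ratio_test, wald_test
from adjnorm.synth import SimulationConfig, simulate_paired_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    study = simulate_paired_study(SimulationConfig(seed=args.seed))

    # clinical-only baseline
    risk, spec, fit = clinical_cox_predictor(study.normal)
    c_clin = concordance_index(study.normal.time, study.normal.event, risk)
    z, p = wald_test(fit)
    _, p_lr = likelihood_ratio_test(fit)
    clin = pd.DataFrame({"covariate": list(spec), "coef": fit.coefficients,
                         "se": fit.standard_errors, "wald_z": z, "wald_p": p})
    clin.to_csv(args.out_dir / "clinical_cox.tsv", sep="\t", index=False)
    print(f"clinical Cox (age+stage): C-index {c_clin:.3f}, LR p {p_lr:.2g}")
    for _, row in clin.iterrows():
        print(f"  {row['covariate']}: coef {row['coef']:+.3f}, Wald p {row['wald_p']:.2g}")

    # informative-gene density per tissue
    rows = []
    for tissue in ("normal", "tumor"):
        coh = standardize_genes(getattr(study, tissue))
        cvec, frac10 = informative_gene_density(coh.expression.to_numpy(), coh.time, coh.event)
        frac05 = float((abs(cvec - 0.5) >= 0.05).mean())
        pd.DataFrame({"gene": coh.gene_ids, "c_index": cvec}).to_csv(
            args.out_dir / f"informative_genes_{tissue}.tsv", sep="\t", index=False)
        rows.append({"tissue": tissue, "informative_fraction_tau10": frac10,
                     "informative_fraction_tau05": frac05})
        print(f"{tissue}: informative fraction = {frac10:.3f} at tau 0.1, "
              f"{frac05:.3f} at tau 0.05")
    pd.DataFrame(rows).to_csv(args.out_dir / "informative_fraction.tsv", sep="\t", index=False)

    # DE fold change vs per-gene Cox coefficient
    table = paired_de_fallback(study.tumor.expression, study.normal.expression)
    table.write(args.out_dir / "de_table.tsv")
    for tissue in ("normal", "tumor"):
        coh = standardize_genes(getattr(study, tissue))
        r = lfc_vs_coef_correlation(table, coh.expression, coh.time, coh.event)
        print(f"Pearson r(log2FC, univariate Cox coef) on {tissue}: {r:+.3f}")
    print("with DEGs planted independently of prognostic genes the correlation "
          "stays near zero: differential expression is not a prognostic filter here")


if __name__ == "__main__":
    main()
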