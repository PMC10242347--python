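#!/usr/bin/env python
"""Cross-cohort prognostic similarity per tissue.

For each simulated discovery/screening cohort pair, fits a univariate Cox
model per gene on the screening cohort and correlates its training
C-index with the test C-index obtained on the discovery cohort.  A high
Pearson r means per-gene prognostic value transfers between cohorts —
the condition under which external-cohort screening can work.
"""

import argparse
from pathlib import Path

from adjnorm.pipeline import cross_cohort_similarity_analysis


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    df = cross_cohort_similarity_analysis(n_seeds=args.n_seeds, seed=args.seed)
    df.to_csv(args.out_dir / "cross_cohort_similarity.tsv", sep="\t", index=False)
    wide = df.pivot(index="seed", columns="tissue", values="pearson_r")
    print(wide.round(3).to_string())
    print(f"mean r: normal {wide['normal'].mean():.3f}, tumor {wide['tumor'].mean():.3f}")
    print("normal-tissue effects are mostly shared across cohorts while tumor "
          "effects are re-drawn, so per-gene prognostic value transfers for "
          "normal tissue but not for tumor tissue — the asymmetry that makes "
          "external screening effective only on the normal arm")


if __name__ == "__main__":
    main()
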