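# adjnorm — prognostic analysis of paired tumor / adjacent-normal transcriptomes

When a cancer cohort profiles both the tumor and the adjacent
histologically normal tissue of each patient, the normal tissue is usually
demoted to a "control" for differential expression.  `adjnorm` implements
the opposite analysis: treat each tissue (and the tumor/normal expression
ratios of DEGs) as a candidate prognostic feature set, evaluate them
head-to-head with survival models over shared cross-validation splits, and
test whether screening genes against an *external* cohort — by distance
correlation with a clinical Cox risk score — improves prediction.  It is
written for computational biologists who want these protocols as a tested,
reusable library rather than a one-off script pile.

The core model is the Cox proportional-hazards framework,
`h(t|x) = h0(t) exp(f(x))`, with two implementations of `f`: a linear model
fitted by Newton–Raphson, and a small neural network `h_θ(x)` (two hidden
layers of width ⌈√d⌉) trained by minimizing the regularized negative
partial log-likelihood

    L(θ) = − Σ_{i:E_i=1} [ h_θ(x_i) − log Σ_{j: t_j ≥ t_i} exp h_θ(x_j) ] + λ‖θ‖²

where `E_i` is the death indicator and `t_i` the follow-up time.  Models
are compared by Harrell's concordance index over repeated 70/30 hold-out
splits, with paired Wilcoxon tests across arms; risk groups split at the
median predicted risk are compared by Kaplan–Meier/log-rank.  Gene
screening ranks genes by Székely's distance correlation between expression
and the linear predictor of a clinical-covariate Cox model fitted on the
screening cohort.  A synthetic paired-cohort generator with planted
prognostic genes, planted DEGs, and a derived screening cohort (shared
normal-tissue effects, divergent tumor effects) makes the whole chain
runnable and testable offline.

## Layout

    src/adjnorm/        library: synth, preprocess, survival, features,
                        screening, models, experiments, pipeline
    analysis/           numbered narrative drivers (simulate → baselines →
                        data-type comparison → screening/sweep → similarity)
    tests/              pytest suite incl. end-to-end acceptance properties
    scripts/acceptance.py   recomputes the headline numbers, writes JSON
    docs/methods.md     full model/procedure documentation

## Worked example

```python
from adjnorm.pipeline import run_headline_analysis

res = run_headline_analysis(n_repeats=20, seed=1)
print(res["mean_c"])
print(res["comparisons"][["group_a", "group_b", "p"]])
```

On the default study conditions (300 patients, 500 genes, 30 prognostic
genes planted only through normal tissue at log-hazard 0.6 per gene, 30%
censoring, screening cohort with 90% shared normal effects and 90%
re-drawn tumor effects) this prints:

    {'normal': 0.6347, 'normal_screened': 0.6598,
     'tumor': 0.4904, 'tumor_screened': 0.4829}

    normal          vs tumor  p = 1.9e-06
    normal_screened vs normal p = 0.024
    tumor_screened  vs tumor  p = 0.47

Read: adjacent-normal expression predicts held-out survival (mean test
C-index 0.63) while tumor expression sits at chance, because that is where
the signal was planted; external-cohort dCor screening at the planted gene
count lifts the normal arm to 0.66 (28 of the 30 selected genes are truly
prognostic) and does nothing for the signal-free tumor arm.  The analysis
scripts tell the same story stepwise, e.g.

    $ python analysis/05_cross_cohort_similarity.py
    mean r: normal 0.320, tumor 0.030

— per-gene prognostic value transfers across cohorts for normal tissue but
not for tumor tissue, which is exactly why screening helps only the normal
arm.

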