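"""Evaluation protocols for comparing prognostic data types and models.

The central protocol is repeated hold-out: per repetition one
event-stratified 70/30 patient split is drawn and *reused* for every model
and every data type (tumor expression, adjacent-normal expression, the two
DEG-ratio feature sets, clinical covariates), so per-repetition C-indices
are paired across arms and can be compared with Wilcoxon tests.
Standardization statistics are estimated on the training fold and applied
to the test fold by default (leakage-safe); a "global" mode standardizes
the whole matrix once, reproducing pipelines that normalize before
splitting.

Supporting analyses: per-gene univariate C-index distributions (informative
gene density), feature-size sweeps over a screening ranking, Kaplan–Meier
risk stratification at the median predicted risk, cross-cohort prognostic
similarity (per-gene train/test C-index correlation between a screening and
an evaluation cohort), and the correlation between DE log-fold changes and
univariate Cox coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .preprocess import standardize_matrix
from .screening import ScreeningRanking, top_k
from .survival import (
    concordance_index,
    fit_cox,
    kaplan_meier,
    logrank_test,
    pearson_correlation,
    wilcoxon_ranksum,
)
from .features import benjamini_hochberg

logger = logging.getLogger("adjnorm")

__all__ = [
    "repeated_holdout",
    "informative_gene_density",
    "feature_size_sweep",
    "median_risk_grouping",
    "cross_cohort_similarity",
    "lfc_vs_coef_correlation",
    "compare_groups",
]


def _stratified_split(event, train_frac, rng):
    """One event-stratified train/test split as boolean masks."""
    event = np.asarray(event)
    train = np.zeros(len(event), dtype=bool)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        train[idx[:n_train]] = True
    return train


def repeated_holdout(datasets: dict, models: dict, time, event,
                     n_repeats: int = 50, train_frac: float = 0.7, seed: int = 0,
                     standardize: str = "train", return_splits: bool = False):
    """Repeated 70/30 hold-out evaluation with shared splits.

    ``datasets`` maps data-type name -> samples × features array/DataFrame
    (all over the same patients, aligned with ``time``/``event``);
    ``models`` maps model name -> zero-argument factory returning a
    fit/predict_risk object.  Every (data type, model) pair within a
    repetition sees the identical split.  Returns an evaluation table with
    columns (data_type, model, repetition, split_id, c_index).
    """
    if standardize not in ("train", "global", "none"):
        raise ValueError("standardize must be 'train', 'global' or 'none'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    mats = {}
    for name, X in datasets.items():
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(time):
            raise ValueError(f"data type {name!r} does not match the patient universe")
        mats[name] = standardize_matrix(X)[0] if standardize == "global" else X
    rng = np.random.default_rng(seed)
    rows = []
    splits = []
    rep = 0
    attempts = 0
    while rep < n_repeats:
        attempts += 1
        if attempts > 20 * n_repeats:
            raise RuntimeError("could not draw usable splits")
        train = _stratified_split(event, train_frac, rng)
        test = ~train
        if event[train].sum() < 1 or event[test].sum() < 1:
            logger.info("repetition redrawn: a fold had no events")
            continue
        split_id = f"rep{rep:03d}"
        ok = True
        new_rows = []
        for dname, X in mats.items():
            if standardize == "train":
                Xtr, mu, sd = standardize_matrix(X[train])
                Xte = (X[test] - mu) / sd
            else:
                Xtr, Xte = X[train], X[test]
            for mname, factory in models.items():
                model = factory()
                model.fit(Xtr, time[train], event[train])
                risk = model.predict_risk(Xte)
                try:
                    c = concordance_index(time[test], event[test], risk)
                except ValueError:
                    logger.info("repetition redrawn: no comparable test pairs")
                    ok = False
                    break
                new_rows.append({"data_type": dname, "model": mname, "repetition": rep,
                                 "split_id": split_id, "c_index": c})
            if not ok:
                break
        if ok:
            rows.extend(new_rows)
            splits.append(train)
            rep += 1
    table = pd.DataFrame(rows)
    return (table, splits) if return_splits else table


def informative_gene_density(expression, time, event, tau: float = 0.1):
    """Univariate per-gene C-index vector and the informative fraction.

    Each gene is fitted alone in a Cox model on the (standardized)
    expression and scored by C-index on the same cohort; genes whose fit
    fails are assigned the chance value 0.5.  The informative fraction is
    the share of genes with |C - 0.5| >= tau.
    """
    X = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    cvec = np.full(X.shape[1], 0.5)
    n_failed = 0
    for j in range(X.shape[1]):
        try:
            fit = fit_cox(X[:, j : j + 1], time, event)
            cvec[j] = concordance_index(time, event, fit.coefficients[0] * X[:, j])
        except Exception:
            n_failed += 1
    if n_failed:
        logger.info("informative_gene_density: %d gene fits failed (C set to 0.5)", n_failed)
    fraction = float(np.mean(np.abs(cvec - 0.5) >= tau))
    return cvec, fraction


def feature_size_sweep(ranking: ScreeningRanking, sizes, expression: pd.DataFrame,
                       time, event, model_factory, n_iter: int = 20,
                       train_frac: float = 0.7, seed: int = 0) -> pd.DataFrame:
    """Mean hold-out C-index at each top-k feature size plus the
    no-selection baseline (all genes, same splits/seed)."""
    sizes = list(sizes)
    n_genes = expression.shape[1]
    if any(k > n_genes or k < 1 for k in sizes):
        raise ValueError(f"feature sizes must lie in [1, {n_genes}]")
    out = []

    def run(X, label, size):
        tab = repeated_holdout({label: X}, {"model": model_factory}, time, event,
                               n_repeats=n_iter, train_frac=train_frac, seed=seed)
        out.append({"size": size, "label": label, "mean_c": float(tab["c_index"].mean()),
                    "sd_c": float(tab["c_index"].std(ddof=1))})

    run(expression.to_numpy(float), "baseline", n_genes)
    for k in sizes:
        genes = top_k(ranking, k)
        run(expression.loc[:, genes].to_numpy(float), f"top{k}", k)
    return pd.DataFrame(out)


def median_risk_grouping(risk, time, event):
    """Split patients at the median predicted risk and compare survival.

    Ties at the median go to the low-risk group.  Returns a dict with the
    per-group Kaplan–Meier curves, group masks and the log-rank p-value.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(risk) < 4:
        raise ValueError("need at least 4 samples to form risk groups")
    med = np.median(risk)
    low = risk <= med
    high = ~low
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("risk scores do not separate at the median")
    chi2, p = logrank_test(time[high], event[high], time[low], event[low])
    km_high = kaplan_meier(time[high], event[high])
    km_low = kaplan_meier(time[low], event[low])
    return {"p": p, "chi2": chi2, "high": high, "low": low,
            "km_high": km_high, "km_low": km_low}


def cross_cohort_similarity(screen_expr, screen_time, screen_event,
                            eval_expr, eval_time, eval_event):
    """Per-gene prognostic similarity between two cohorts.

    For each common gene a univariate Cox model is fitted on the screening
    cohort; its training C-index (screening cohort) and test C-index
    (evaluation cohort, same fitted coefficient) are recorded and their
    Pearson correlation across genes returned.  Both matrices must already
    be restricted to a shared, identically ordered gene universe.
    """
    Xs = np.asarray(screen_expr, dtype=float)
    Xe = np.asarray(eval_expr, dtype=float)
    if Xs.shape[1] != Xe.shape[1]:
        raise ValueError("cohorts must share the gene universe (run intersect_genes first)")
    genes = (list(screen_expr.columns) if isinstance(screen_expr, pd.DataFrame)
             else [f"g{j}" for j in range(Xs.shape[1])])
    rows = []
    n_skipped = 0
    for j in range(Xs.shape[1]):
        try:
            fit = fit_cox(Xs[:, j : j + 1], screen_time, screen_event)
            beta = fit.coefficients[0]
            c_train = concordance_index(screen_time, screen_event, beta * Xs[:, j])
            c_test = concordance_index(eval_time, eval_event, beta * Xe[:, j])
            rows.append({"gene": genes[j], "train_c": c_train, "test_c": c_test})
        except Exception:
            n_skipped += 1
    if n_skipped:
        logger.info("cross_cohort_similarity: skipped %d genes", n_skipped)
    df = pd.DataFrame(rows)
    r = pearson_correlation(df["train_c"].to_numpy(), df["test_c"].to_numpy())
    return df, r


def lfc_vs_coef_correlation(de_table, expression, time, event):
    """Pearson correlation between per-gene DE log2 fold changes and
    univariate Cox coefficients on the given tissue matrix."""
    genes = [g for g in de_table.gene_ids if g in set(expression.columns)]
    if not genes:
        raise ValueError("no genes shared between the DE table and the cohort")
    lfc = {g: v for g, v in zip(de_table.gene_ids, de_table.log2fc)}
    X = expression.loc[:, genes].to_numpy(float)
    coefs = np.full(len(genes), np.nan)
    for j in range(len(genes)):
        try:
            coefs[j] = fit_cox(X[:, j : j + 1], time, event).coefficients[0]
        except Exception:
            pass
    keep = np.isfinite(coefs)
    lfc_vec = np.array([lfc[g] for g in genes])[keep]
    return pearson_correlation(lfc_vec, coefs[keep])


def _filter(eval_table: pd.DataFrame, spec: dict) -> pd.DataFrame:
    out = eval_table
    for col, val in spec.items():
        out = out[out[col] == val]
    return out


def compare_groups(eval_table: pd.DataFrame, comparisons, adjust: str = "bh") -> pd.DataFrame:
    """Wilcoxon comparisons of C-index distributions between arm pairs.

    ``comparisons`` is a list of (spec_a, spec_b) dicts filtering the
    evaluation table (e.g. ``{"data_type": "normal"}`` vs
    ``{"data_type": "tumor"}``); a single pair may be passed directly.
    When both arms cover identical split ids the comparison is paired
    (signed-rank across shared splits); otherwise the rank-sum test is
    used.  Adjusted p-values are BH across all comparisons in the call.
    """
    if isinstance(comparisons, tuple) and len(comparisons) == 2 and isinstance(comparisons[0], dict):
        comparisons = [comparisons]
    rows = []
    for spec_a, spec_b in comparisons:
        a = _filter(eval_table, spec_a)
        b = _filter(eval_table, spec_b)
        if a.empty or b.empty:
            raise ValueError(f"empty comparison group: {spec_a} vs {spec_b}")
        paired = (len(a) == len(b)) and (sorted(a["split_id"]) == sorted(b["split_id"]))
        if paired:
            av = a.sort_values("split_id")["c_index"].to_numpy()
            bv = b.sort_values("split_id")["c_index"].to_numpy()
            diff = av - bv
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(_sps.wilcoxon(av, bv).pvalue)
            test = "signed_rank"
        else:
            _, p = wilcoxon_ranksum(a["c_index"].to_numpy(), b["c_index"].to_numpy())
            test = "rank_sum"
        rows.append({"group_a": str(spec_a), "group_b": str(spec_b), "test": test,
                     "mean_a": float(a["c_index"].mean()), "mean_b": float(b["c_index"].mean()),
                     "p": p})
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    elif adjust in (None, "none"):
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df
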