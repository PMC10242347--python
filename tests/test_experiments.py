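"""Evaluation protocols: repeated hold-out, informative-gene density,
sweeps, KM risk grouping, cross-cohort similarity, group comparisons."""

import numpy as np
import pandas as pd
import pytest

from adjnorm.experiments import (
    compare_groups,
    cross_cohort_similarity,
    feature_size_sweep,
    informative_gene_density,
    lfc_vs_coef_correlation,
    median_risk_grouping,
    repeated_holdout,
)
from adjnorm.features import DETable
from adjnorm.models import CoxPHModel
from adjnorm.preprocess import standardize_genes, standardize_matrix
from adjnorm.screening import screen_genes
from adjnorm.survival import concordance_index, fit_cox
from adjnorm.synth import SimulationConfig, simulate_paired_study

from conftest import random_survival


def _toy_data(seed=0, n=150, d=3, coef=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    _, t, e = random_survival(rng, n, censor=0.3, risk_coef=coef, x=X[:, 0])
    return X, t, e


# ------------------------------------------------------------- hold-out


def test_holdout_transparent_single_repetition():
    """One repetition reproduces a direct fit/evaluate computation."""
    X, t, e = _toy_data()
    tab, splits = repeated_holdout({"d": X}, {"cox": CoxPHModel}, t, e,
                                   n_repeats=1, seed=11, return_splits=True)
    train = splits[0]
    test = ~train
    Xtr, mu, sd = standardize_matrix(X[train])
    Xte = (X[test] - mu) / sd
    fit = fit_cox(Xtr, t[train], e[train])
    c_direct = concordance_index(t[test], e[test], Xte @ fit.coefficients)
    assert tab["c_index"].iloc[0] == pytest.approx(c_direct, abs=1e-12)


def test_holdout_shared_splits_across_calls():
    """The identical seed yields identical split masks, so C-indices from
    separate per-arm calls are paired."""
    X, t, e = _toy_data()
    _, s1 = repeated_holdout({"a": X}, {"cox": CoxPHModel}, t, e,
                             n_repeats=4, seed=3, return_splits=True)
    _, s2 = repeated_holdout({"b": X + 1.0}, {"cox": CoxPHModel}, t, e,
                             n_repeats=4, seed=3, return_splits=True)
    for m1, m2 in zip(s1, s2):
        np.testing.assert_array_equal(m1, m2)


def test_holdout_chance_level_on_permuted_times():
    # average over replicates: any single permuted dataset keeps a chance
    # covariate/time correlation that both folds share
    tabs = []
    for rep in range(8):
        X, t, e = _toy_data(seed=100 + rep, n=300, coef=1.0)
        perm = np.random.default_rng(rep).permutation(len(t))
        tabs.append(repeated_holdout({"x": X, "x2": X**2}, {"cox": CoxPHModel},
                                     t[perm], e[perm], n_repeats=4, seed=rep))
    tab = pd.concat(tabs, ignore_index=True)
    for _, grp in tab.groupby("data_type"):
        assert grp["c_index"].mean() == pytest.approx(0.5, abs=0.03)


def test_holdout_event_stratified_splits():
    X, t, e = _toy_data(seed=9)
    _, splits = repeated_holdout({"x": X}, {"cox": CoxPHModel}, t, e,
                                 n_repeats=5, seed=1, return_splits=True)
    for train in splits:
        frac_train_events = e[train].sum() / e.sum()
        assert 0.6 < frac_train_events < 0.8  # ~70% of events in train


# ------------------------------------------------- informative genes


def test_informative_density_null_fraction_small():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((200, 100))
    _, t, e = random_survival(rng, 200, censor=0.3)
    cvec, frac = informative_gene_density(X, t, e, tau=0.1)
    assert cvec.shape == (100,)
    assert frac <= 0.05


def test_informative_density_perfect_gene():
    rng = np.random.default_rng(6)
    n = 80
    t = np.sort(rng.exponential(1.0, n)) + 1e-3
    e = np.ones(n, dtype=int)
    X = np.column_stack([-t, rng.standard_normal(n)])  # first gene ranks time
    cvec, _ = informative_gene_density(X, t, e)
    assert cvec[0] > 0.95


# ----------------------------------------------------------- sweeps


def test_sweep_full_size_matches_baseline():
    rng = np.random.default_rng(12)
    n, g = 120, 12
    expr = pd.DataFrame(rng.standard_normal((n, g)), columns=[f"g{j}" for j in range(g)])
    _, t, e = random_survival(rng, n, censor=0.2, risk_coef=0.8, x=expr["g0"].to_numpy())
    ranking = screen_genes(expr, expr["g0"].to_numpy())
    out = feature_size_sweep(ranking, [g], expr, t, e, CoxPHModel, n_iter=4, seed=7)
    base = out[out["label"] == "baseline"]["mean_c"].iloc[0]
    full = out[out["label"] == f"top{g}"]["mean_c"].iloc[0]
    assert full == pytest.approx(base, abs=1e-12)


def test_sweep_random_ranking_does_not_beat_baseline():
    rng = np.random.default_rng(13)
    n, g = 150, 40
    expr = pd.DataFrame(rng.standard_normal((n, g)), columns=[f"g{j:02d}" for j in range(g)])
    _, t, e = random_survival(rng, n, censor=0.3)  # pure noise outcome
    noise_rank = screen_genes(expr, rng.standard_normal(n))
    out = feature_size_sweep(noise_rank, [5, 20], expr, t, e, CoxPHModel, n_iter=6, seed=3)
    base = out[out["label"] == "baseline"]["mean_c"].iloc[0]
    assert (out[out["label"] != "baseline"]["mean_c"] < base + 0.08).all()


def test_sweep_size_bounds_checked():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
    ranking = screen_genes(expr, rng.standard_normal(30))
    with pytest.raises(ValueError):
        feature_size_sweep(ranking, [6], expr, np.arange(1.0, 31.0), np.ones(30), CoxPHModel)


# ------------------------------------------------------ KM risk groups


def test_median_grouping_identical_risks_error():
    with pytest.raises(ValueError):
        median_risk_grouping(np.ones(10), np.arange(1.0, 11.0), np.ones(10))


def test_median_grouping_strong_signal_significant():
    rng = np.random.default_rng(3)
    n = 200
    risk = rng.standard_normal(n)
    t = rng.exponential(1.0, n) / np.exp(1.5 * risk)
    out = median_risk_grouping(risk, np.maximum(t, 1e-9), np.ones(n))
    assert out["p"] < 0.05
    assert out["high"].sum() + out["low"].sum() == n


def test_median_grouping_null_p_roughly_uniform():
    from scipy import stats as sps

    rng = np.random.default_rng(14)
    ps = []
    for _ in range(200):
        n = 80
        risk = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.7).astype(int)
        if e.sum() == 0:
            continue
        ps.append(median_risk_grouping(risk, t, e)["p"])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# --------------------------------------------- cross-cohort similarity


def test_cross_cohort_identity_r_is_one(small_study):
    coh = standardize_genes(small_study.normal)
    df, r = cross_cohort_similarity(coh.expression, coh.time, coh.event,
                                    coh.expression, coh.time, coh.event)
    np.testing.assert_allclose(df["train_c"], df["test_c"])
    assert r == pytest.approx(1.0)


def test_cross_cohort_independent_cohorts_r_near_zero():
    cfg_a = SimulationConfig(n_patients=150, n_genes=500, n_prog_normal=0, n_prog_tumor=0,
                             beta_normal=0.0, beta_tumor=0.0, n_deg=0, seed=31)
    cfg_b = SimulationConfig(**{**cfg_a.__dict__, "seed": 32})
    a = standardize_genes(simulate_paired_study(cfg_a).normal)
    b = standardize_genes(simulate_paired_study(cfg_b).normal)
    _, r = cross_cohort_similarity(a.expression, a.time, a.event,
                                   b.expression, b.time, b.event)
    assert abs(r) < 0.15


# ------------------------------------------------- LFC vs Cox coefficient


def test_lfc_coef_correlation_aligned_planting():
    cfg = SimulationConfig(n_patients=250, n_genes=300, n_prog_normal=25, n_prog_tumor=0,
                           beta_normal=0.8, beta_tumor=0.0, n_deg=25,
                           deg_on_prognostic=True, seed=17)
    study = simulate_paired_study(cfg)
    degs = set(study.truth["degs"])
    assert degs == set(study.truth["prognostic_normal"])
    table = DETable(gene_ids=study.normal.gene_ids,
                    log2fc=np.array([3.0 if g in degs else 0.0 for g in study.normal.gene_ids]),
                    padj=np.full(cfg.n_genes, 0.01))
    coh = standardize_genes(study.normal)
    r = lfc_vs_coef_correlation(table, coh.expression, coh.time, coh.event)
    assert r > 0.3


def test_lfc_coef_correlation_independent_planting():
    cfg = SimulationConfig(n_patients=250, n_genes=300, n_prog_normal=25, n_prog_tumor=0,
                           beta_normal=0.8, beta_tumor=0.0, n_deg=25, seed=18)
    study = simulate_paired_study(cfg)
    degs = set(study.truth["degs"])
    assert degs.isdisjoint(study.truth["prognostic_normal"])
    table = DETable(gene_ids=study.normal.gene_ids,
                    log2fc=np.array([3.0 if g in degs else 0.0 for g in study.normal.gene_ids]),
                    padj=np.full(cfg.n_genes, 0.01))
    coh = standardize_genes(study.normal)
    r = lfc_vs_coef_correlation(table, coh.expression, coh.time, coh.event)
    assert abs(r) < 0.15


def test_lfc_coef_correlation_zero_variance_errors(small_study):
    coh = standardize_genes(small_study.normal)
    table = DETable(gene_ids=coh.gene_ids, log2fc=np.zeros(coh.n_genes),
                    padj=np.full(coh.n_genes, 0.5))
    with pytest.raises(ValueError):
        lfc_vs_coef_correlation(table, coh.expression, coh.time, coh.event)


# ------------------------------------------------------ group comparison


def _eval_table(rng, mean_a, mean_b, n=50, paired=True):
    rows = []
    for i in range(n):
        rows.append({"data_type": "A", "model": "nn", "repetition": i,
                     "split_id": f"rep{i:03d}", "c_index": rng.normal(mean_a, 0.05)})
        sid = f"rep{i:03d}" if paired else f"other{i:03d}"
        rows.append({"data_type": "B", "model": "nn", "repetition": i,
                     "split_id": sid, "c_index": rng.normal(mean_b, 0.05)})
    return pd.DataFrame(rows)


def test_compare_identical_groups_p_one(rng):
    tab = _eval_table(rng, 0.6, 0.6)
    tab.loc[tab["data_type"] == "B", "c_index"] = tab.loc[tab["data_type"] == "A", "c_index"].to_numpy()
    out = compare_groups(tab, ({"data_type": "A"}, {"data_type": "B"}))
    assert out["p"].iloc[0] == 1.0


def test_compare_detects_shifted_distributions(rng):
    tab = _eval_table(rng, 0.6, 0.5)
    out = compare_groups(tab, [({"data_type": "A"}, {"data_type": "B"})])
    assert out["test"].iloc[0] == "signed_rank"
    assert out["p_adj"].iloc[0] < 0.05


def test_compare_unpaired_falls_back_to_ranksum(rng):
    tab = _eval_table(rng, 0.6, 0.5, paired=False)
    out = compare_groups(tab, [({"data_type": "A"}, {"data_type": "B"})])
    assert out["test"].iloc[0] == "rank_sum"
    assert out["p"].iloc[0] < 0.05


def test_compare_single_comparison_adjustment_is_identity(rng):
    tab = _eval_table(rng, 0.58, 0.55)
    out = compare_groups(tab, [({"data_type": "A"}, {"data_type": "B"})])
    assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])


def test_compare_missing_group_errors(rng):
    tab = _eval_table(rng, 0.6, 0.5)
    with pytest.raises(ValueError):
        compare_groups(tab, ({"data_type": "A"}, {"data_type": "missing"}))
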