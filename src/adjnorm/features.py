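"""Differential-expression features: DEG calling, log expression ratios,
fold-change ranking and multiplicity adjustment.

A DEG here is a gene with |log2 fold change| strictly greater than 2 and
BH-adjusted p strictly below 0.05 (both thresholds configurable).  DE
results are normally ingested from an external table (e.g. a DESeq2 export
with columns gene, log2fc, padj); :func:`paired_de_fallback` provides a
clearly-labelled paired-test substitute on log2(x+1) values for cohorts
where no external table exists — it is *not* a negative-binomial GLM.

The two per-patient ratio features are natural-log ratios of tumor to
normal expression: against the patient's own normal profile
(``ratio_individual``, ln(T_ij / N_ij)) or against the cohort median normal
profile (``ratio_median``, ln(T_ij / median_i N_ij)).  Zeros in FPKM-like
data are handled by an explicit pseudocount added to both numerator and
denominator before the log (default 1; set 0 to reproduce the bare
formulas on strictly positive data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DETable",
    "identify_degs",
    "paired_de_fallback",
    "benjamini_hochberg",
    "ratio_individual",
    "ratio_median",
    "ratio_features",
    "rank_by_abs_lfc",
]


@dataclass
class DETable:
    """Per-gene differential-expression summary (tumor vs. normal)."""

    gene_ids: list
    log2fc: np.ndarray
    padj: np.ndarray
    method: str = "external"

    def __post_init__(self):
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.padj = np.asarray(self.padj, dtype=float)
        if not (len(self.gene_ids) == len(self.log2fc) == len(self.padj)):
            raise ValueError("gene_ids, log2fc and padj must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any((self.padj < 0) | (self.padj > 1)):
            raise ValueError("padj must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "log2fc": self.log2fc, "padj": self.padj})

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "DETable":
        df = pd.read_csv(path, sep=sep)
        return cls(gene_ids=list(df["gene"].astype(str)), log2fc=df["log2fc"].to_numpy(),
                   padj=df["padj"].to_numpy(), method="external")


def identify_degs(table: DETable, lfc_cut: float = 2.0, padj_cut: float = 0.05) -> list:
    """Genes with |log2fc| > lfc_cut AND padj < padj_cut (strict inequalities)."""
    mask = (np.abs(table.log2fc) > lfc_cut) & (table.padj < padj_cut)
    return [g for g, m in zip(table.gene_ids, mask) if m]


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_de_fallback(tumor_expr: pd.DataFrame, normal_expr: pd.DataFrame,
                       pairing=None, method: str = "ttest") -> DETable:
    """Paired differential-expression test on log2(x + 1) values.

    ``pairing`` maps tumor sample id -> normal sample id (same-index
    identity assumed when omitted).  ``method`` is ``ttest`` (paired t) or
    ``signed_rank`` (Wilcoxon signed-rank).  log2fc is the mean paired
    log2(x+1) difference; padj is BH-adjusted.  This is a simple fallback
    for synthetic or pre-normalized data, not a count-model DE method.
    """
    if pairing is not None:
        normal_expr = normal_expr.loc[[pairing[s] for s in tumor_expr.index]]
    if list(tumor_expr.columns) != list(normal_expr.columns):
        raise ValueError("tumor and normal matrices must share gene columns")
    if tumor_expr.shape[0] != normal_expr.shape[0]:
        raise ValueError("tumor and normal matrices must have matching samples")
    if tumor_expr.shape[0] < 3:
        raise ValueError("need at least 3 patient pairs")
    d = np.log2(tumor_expr.to_numpy(float) + 1.0) - np.log2(normal_expr.to_numpy(float) + 1.0)
    log2fc = d.mean(axis=0)
    if method == "ttest":
        pvals = _sps.ttest_rel(np.log2(tumor_expr.to_numpy(float) + 1.0),
                               np.log2(normal_expr.to_numpy(float) + 1.0), axis=0).pvalue
    elif method == "signed_rank":
        pvals = np.array([
            _sps.wilcoxon(col).pvalue if np.any(col != 0) else 1.0 for col in d.T
        ])
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # constant-difference columns
    return DETable(gene_ids=list(tumor_expr.columns), log2fc=log2fc,
                   padj=benjamini_hochberg(pvals), method=f"paired_{method}_fallback")


def _log_ratio(num, den, pseudocount):
    num = np.asarray(num, dtype=float) + pseudocount
    den = np.asarray(den, dtype=float) + pseudocount
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError("expression values must be positive after pseudocount")
    return np.log(num / den)


def ratio_individual(tumor, normal, pseudocount: float = 1.0):
    """ln(tumor / normal) per patient against the patient's own normal value."""
    return _log_ratio(tumor, normal, pseudocount)


def ratio_median(tumor, normal_column, pseudocount: float = 1.0):
    """ln(tumor / median(normal)) against the cohort median normal value.

    ``tumor`` may be a scalar or per-patient vector for one gene;
    ``normal_column`` is that gene's normal-tissue values over all patients.
    """
    med = np.median(np.asarray(normal_column, dtype=float))
    return _log_ratio(tumor, med, pseudocount)


def ratio_features(tumor_expr: pd.DataFrame, normal_expr: pd.DataFrame,
                   genes=None, kind: str = "individual", pseudocount: float = 1.0) -> pd.DataFrame:
    """Patient × gene matrix of log expression ratios for the chosen genes."""
    if genes is None:
        genes = list(tumor_expr.columns)
    t = tumor_expr.loc[:, genes].to_numpy(float)
    n = normal_expr.loc[:, genes].to_numpy(float)
    if kind == "individual":
        vals = ratio_individual(t, n, pseudocount)
    elif kind == "median":
        med = np.median(n, axis=0)
        vals = _log_ratio(t, med[None, :], pseudocount)
    else:
        raise ValueError(f"unknown ratio kind {kind!r}")
    return pd.DataFrame(vals, index=tumor_expr.index, columns=genes)


def rank_by_abs_lfc(table: DETable) -> list:
    """Genes ordered by |log2fc| descending, ties broken by gene id."""
    order = sorted(range(len(table.gene_ids)),
                   key=lambda i: (-abs(table.log2fc[i]), str(table.gene_ids[i])))
    return [table.gene_ids[i] for i in order]
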