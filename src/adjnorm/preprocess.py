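"""Cohort container, delimited-text I/O and expression preprocessing.

A :class:`SurvivalCohort` bundles a samples × genes expression matrix with
survival outcomes (follow-up time and a 0/1 death indicator), per-sample
clinical covariates (age in years, ordinal tumor stage 1–4, optional binary
metastasis), a tissue label and an optional patient-id pairing used to match
tumor samples with adjacent-normal samples from the same patient.

Preprocessing follows the bulk-RNA-seq conventions this pipeline targets:
genes with zero mean (all-zero columns in nonnegative FPKM-like data) are
discarded, each retained gene is standardized to mean 0 / sd 1 across
samples (sample sd, ddof=1 — fixed for reproducibility), and cohorts
from different sources are restricted to their common gene set before any
cross-cohort step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("adjnorm")

CLINICAL_COLUMNS = ("patient_id", "time", "event", "age", "stage")


class ParseError(ValueError):
    """Malformed delimited input (ragged row, non-numeric cell, duplicate id)."""


@dataclass
class SurvivalCohort:
    """Expression + outcomes for one tissue of one cohort.

    ``expression`` is a samples × genes DataFrame (index = sample ids,
    columns = gene ids); ``time`` and ``event`` are aligned 1-D arrays;
    ``clinical`` is indexed by sample id; ``pairing`` maps sample id to
    patient id when tumor/normal pairing is known.
    """

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    clinical: pd.DataFrame
    tissue: str
    cohort_id: str = "cohort"
    pairing: pd.Series | None = None
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.expression.shape[0]
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event length must match expression rows")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0/1")
        if self.expression.columns.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.tissue not in ("tumor", "normal"):
            raise ValueError("tissue must be 'tumor' or 'normal'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_genes(self, genes) -> "SurvivalCohort":
        return replace(self, expression=self.expression.loc[:, list(genes)])


def read_expression(path, orientation: str = "genes_in_rows", sep: str | None = None) -> pd.DataFrame:
    """Read a delimited expression matrix into samples × genes form.

    ``orientation`` declares the file layout: ``genes_in_rows`` (one row per
    gene, columns are samples — transposed on read) or ``samples_in_rows``.
    Duplicate ids, ragged rows and non-numeric cells raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    ncol = len(header)
    ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != ncol:
            raise ParseError(f"{path}:{lineno}: expected {ncol} fields, got {len(cells)}")
        ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate row ids {dup}")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise ParseError(f"{path}: duplicate column ids in header")
    df = pd.DataFrame(rows, index=ids, columns=col_ids)
    if orientation == "genes_in_rows":
        df = df.T
    df.index.name = "sample"
    df.columns.name = "gene"
    return df


def write_expression(df: pd.DataFrame, path, orientation: str = "genes_in_rows", sep: str = "\t") -> None:
    """Write a samples × genes matrix in the dialect :func:`read_expression` reads."""
    out = df.T if orientation == "genes_in_rows" else df
    out = out.copy()
    out.index.name = "gene" if orientation == "genes_in_rows" else "sample"
    out.to_csv(path, sep=sep)


def read_clinical(path, sep: str | None = None) -> pd.DataFrame:
    """Read a clinical table (patient_id, time, event, age, stage[, metastasis, tissue])."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    return df


def build_cohort(expression: pd.DataFrame, clinical: pd.DataFrame, tissue: str, cohort_id: str = "cohort") -> SurvivalCohort:
    """Match expression samples to clinical rows by exact patient-id string.

    Samples present in only one table are dropped; the count is logged.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    common = [s for s in expression.index if s in clin.index]
    dropped = expression.shape[0] - len(common) + (len(clin) - len(common))
    if dropped:
        logger.info("build_cohort: dropped %d unmatched samples", dropped)
    if not common:
        raise ValueError("no samples shared between expression and clinical tables")
    expr = expression.loc[common]
    clin = clin.loc[common]
    covar_cols = [c for c in ("age", "stage", "metastasis") if c in clin.columns]
    return SurvivalCohort(
        expression=expr,
        time=clin["time"].to_numpy(float),
        event=clin["event"].to_numpy(int),
        clinical=clin[covar_cols].astype(float),
        tissue=tissue,
        cohort_id=cohort_id,
        pairing=pd.Series(clin.index, index=clin.index, name="patient_id"),
    )


def filter_zero_mean_genes(cohort: SurvivalCohort) -> SurvivalCohort:
    """Drop genes whose mean expression is zero (all-zero columns on
    nonnegative data); gene order otherwise preserved."""
    means = cohort.expression.mean(axis=0)
    keep = means != 0.0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_zero_mean_genes: removed %d genes", n_drop)
    return replace(cohort, expression=cohort.expression.loc[:, keep])


def standardize_genes(cohort: SurvivalCohort, ddof: int = 1) -> SurvivalCohort:
    """Standardize each gene to mean 0, sd 1 across samples.

    Constant (zero-variance) genes cannot be standardized and are dropped
    with a logged warning.
    """
    expr = cohort.expression
    sd = expr.std(axis=0, ddof=ddof)
    constant = sd == 0.0
    if constant.any():
        logger.warning("standardize_genes: dropped %d constant genes", int(constant.sum()))
        expr = expr.loc[:, ~constant]
        sd = sd[~constant]
    out = (expr - expr.mean(axis=0)) / sd
    return replace(cohort, expression=out, standardized=True)


def standardize_matrix(X: np.ndarray, ddof: int = 1):
    """Column-standardize a plain array; returns (Z, mean, sd).

    Zero-variance columns are mapped to 0 (sd treated as 1) so that
    train-statistics can be applied to a test block without dropping columns.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def intersect_genes(a: SurvivalCohort, b: SurvivalCohort):
    """Restrict both cohorts to their sorted common gene set (same order)."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("cohorts share no genes")
    return a.subset_genes(common), b.subset_genes(common)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)
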