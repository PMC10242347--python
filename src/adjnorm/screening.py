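"""Distance-correlation gene screening against a clinical risk predictor.

Genes are ranked by the sample distance correlation (Székely's V-statistic
form) between their expression across patients and the linear predictor of
a Cox model fitted on clinical covariates alone (age, stage, metastasis
where available) — typically on an *external* screening cohort, whose
ranking is then applied to the discovery cohort's gene universe.  Distance
correlation captures nonlinear as well as linear association, which is why
it is used instead of Pearson screening.

The estimator: with pairwise absolute-difference matrices A and B
double-centered by row, column and grand means,
``dCov^2 = mean(A * B)``, ``dVar_x = mean(A * A)``, and
``dCor = sqrt(dCov^2 / sqrt(dVar_x dVar_y))``.  A constant variable has
dVar 0; its dCor is defined as 0 here so constant genes never rank.
O(n^2) memory per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SurvivalCohort
from .survival import CoxFit, fit_cox, linear_predictor

__all__ = ["ScreeningRanking", "distance_correlation", "clinical_cox_predictor", "screen_genes", "top_k"]


def _centered_dist(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation in [0, 1] (V-statistic estimator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    A = _centered_dist(x)
    B = _centered_dist(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x == 0.0 or dvar_y == 0.0:
        return 0.0
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


@dataclass
class ScreeningRanking:
    """Genes ordered by distance correlation with a clinical risk predictor."""

    gene_ids: list
    dcor: np.ndarray
    cohort_id: str = "cohort"
    predictor_spec: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dcor = np.asarray(self.dcor, dtype=float)
        if len(self.gene_ids) != len(self.dcor):
            raise ValueError("gene_ids and dcor must have equal length")
        if np.any(np.diff(self.dcor) > 1e-12):
            raise ValueError("dcor must be sorted nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "dcor": self.dcor,
                             "rank": np.arange(1, len(self.gene_ids) + 1)})

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def clinical_cox_predictor(cohort: SurvivalCohort, covariates=None):
    """Per-sample risk score from a Cox fit on clinical covariates only.

    Uses age and stage, plus metastasis when the cohort records it (the
    covariate list can be overridden).  Returns ``(risk, spec, fit)`` where
    ``spec`` names the covariates that entered the model.
    """
    if covariates is None:
        covariates = [c for c in ("age", "stage", "metastasis") if c in cohort.clinical.columns]
    if not covariates:
        raise ValueError("cohort has no clinical covariates")
    X = cohort.clinical[list(covariates)].to_numpy(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(covariates, sd) if s == 0]
        raise ValueError(f"clinical covariates with zero variance: {bad}")
    Z = (X - X.mean(axis=0)) / sd  # standardized for Newton stability
    fit = fit_cox(Z, cohort.time, cohort.event)
    if not fit.converged:
        raise RuntimeError(
            f"clinical Cox model did not converge (|beta|max={np.abs(fit.coefficients).max():.3g}, "
            f"iterations={fit.n_iterations})"
        )
    return linear_predictor(fit, Z), tuple(covariates), fit


def screen_genes(expression: pd.DataFrame, predictor, cohort_id: str = "cohort",
                 predictor_spec: tuple = ()) -> ScreeningRanking:
    """Rank genes by distance correlation with a risk predictor.

    ``expression`` is samples × genes (screen on the standardized matrix for
    consistency with the preprocessing conventions); ties in dCor are broken
    lexicographically by gene id.
    """
    predictor = np.asarray(predictor, dtype=float)
    if expression.shape[0] != len(predictor):
        raise ValueError("expression sample count must equal predictor length")
    B = _centered_dist(predictor)
    dvar_y = (B * B).mean()
    scores = np.zeros(expression.shape[1])
    if dvar_y > 0:
        X = expression.to_numpy(float)
        for j in range(X.shape[1]):
            A = _centered_dist(X[:, j])
            dvar_x = (A * A).mean()
            if dvar_x > 0:
                scores[j] = np.sqrt(max((A * B).mean(), 0.0) / np.sqrt(dvar_x * dvar_y))
    genes = [str(gid) for gid in expression.columns]
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return ScreeningRanking(gene_ids=[genes[i] for i in order], dcor=scores[order],
                            cohort_id=cohort_id, predictor_spec=tuple(predictor_spec))


def top_k(ranking: ScreeningRanking, k: int) -> list:
    """First k gene ids of a screening ranking."""
    if not 1 <= k <= len(ranking.gene_ids):
        raise ValueError(f"k must lie in [1, {len(ranking.gene_ids)}]")
    return ranking.gene_ids[:k]
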