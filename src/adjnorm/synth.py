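"""Synthetic paired tumor / adjacent-normal survival studies.

The generator emulates the study design this pipeline analyzes: each patient
contributes a tumor and an adjacent-normal expression profile, clinical
covariates (age, ordinal stage), a follow-up time and a death indicator.
Prognostic structure is planted per tissue: a chosen set of genes carries a
standardized latent signal ``z`` that enters the proportional-hazards linear
predictor with a per-gene log-hazard effect, so signal can be placed only in
the normal-tissue profiles, only in the tumor profiles, or both.  A second
"screening" cohort can be derived whose normal-tissue gene effects are
largely shared with the discovery cohort while its tumor-tissue effects are
re-drawn — the regime in which external-cohort gene screening helps the
normal arm but not the tumor arm.

Generative model (per patient i, gene g):

* clinical: age ~ U(40, 85); stage ~ categorical on 1–4; both standardized
  into a clinical risk score ``c_i = a_age * age_i + a_stage * stage_i``.
* latent gene signal ``z_ig ~ N(0, 1)`` independent across planted genes.
* hazard: ``h_i = h0 * exp(c_i + sum_g b^N_g z^N_ig + sum_g b^T_g z^T_ig)``;
  survival time by inverse transform from the exponential baseline,
  ``T_i = -log U / h_i``.
* censoring: independent exponential; its rate solves
  ``mean_i rate / (rate + h_i) = censor_rate`` exactly (root-found on the
  realized hazards), so the expected censored fraction matches the request.
* expression (log scale): ``mu_g + s_ig + noise_sd * eps``, exponentiated so
  matrices are nonnegative FPKM-like values.  For a planted gene the
  embedded signal is ``s_ig = sqrt(1 - rho_g^2) z_ig + rho_g c*_i`` where
  ``c*`` is the standardized clinical score and
  ``rho_g = clin_coupling * |b_g| / max|b|`` scales with the gene's hazard
  effect: the gene-specific component drives the hazard while the shared
  component makes strongly prognostic genes detectable by screening against
  a clinical risk predictor, as tumor-burden-correlated transcription is in
  real cohorts.
* differential expression: planted DEG genes get ``deg_log2fc`` added to the
  tumor profile on the log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import SurvivalCohort, write_expression

__all__ = ["SimulationConfig", "PairedStudy", "simulate_paired_study", "simulate_screening_cohort", "write_study"]

_STAGE_PROBS = (0.35, 0.30, 0.25, 0.10)
_AGE_LO, _AGE_HI = 40.0, 85.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic paired cohort.

    Defaults describe a mid-sized discovery cohort with a clear
    normal-tissue prognostic compartment: 300 patients, 500 genes, 30 genes
    prognostic through each tissue at moderate per-gene log-hazard effects,
    ~30% censoring, and a screening cohort that shares 90% of the
    normal-tissue effect structure while its tumor effects are 90% re-drawn.
    """

    n_patients: int = 300
    n_genes: int = 500
    n_prog_normal: int = 30
    n_prog_tumor: int = 30
    beta_normal: float = 0.6
    beta_tumor: float = 0.4
    n_deg: int = 40
    deg_log2fc: float = 3.0
    clin_effects: tuple[float, float] = (0.5, 0.7)  # (age, stage) on standardized scale
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    noise_sd: float = 0.3
    shared_normal_fraction: float = 0.9
    tumor_divergence: float = 0.9
    clin_coupling: float = 0.35
    deg_on_prognostic: bool = False  # plant DEGs on the normal-prognostic genes
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_genes) < 1:
            raise ConfigurationError("n_patients and n_genes must be positive")
        for name in ("n_prog_normal", "n_prog_tumor", "n_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_prog_normal + self.n_prog_tumor > self.n_genes:
            raise ConfigurationError("planted prognostic genes exceed n_genes")
        if self.n_deg > self.n_genes:
            raise ConfigurationError("n_deg exceeds n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for name in ("shared_normal_fraction", "clin_coupling"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.tumor_divergence <= 1.0:
            raise ConfigurationError("tumor_divergence must lie in [0, 1]")


@dataclass
class PairedStudy:
    """A matched tumor/normal cohort plus the ground truth that generated it."""

    tumor: SurvivalCohort
    normal: SurvivalCohort
    pairing: pd.Series
    truth: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return self.tumor.n_samples


def _censoring_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Rate c of an independent exponential censor with
    ``mean_i c / (c + h_i) = censor_rate`` (0 means no censoring)."""
    if censor_rate == 0.0:
        return 0.0

    def f(logc):
        c = np.exp(logc)
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = -30.0, 30.0
    lo = min(lo, np.log(hazards.min()) - 10)
    hi = max(hi, np.log(hazards.max()) + 10)
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))


def _standardized_clinical(age, stage, clin_effects):
    age_std = (age - (_AGE_LO + _AGE_HI) / 2.0) / ((_AGE_HI - _AGE_LO) / np.sqrt(12.0))
    probs = np.asarray(_STAGE_PROBS)
    stage_mean = np.sum(probs * np.arange(1, 5))
    stage_sd = np.sqrt(np.sum(probs * (np.arange(1, 5) - stage_mean) ** 2))
    stage_std = (stage - stage_mean) / stage_sd
    c = clin_effects[0] * age_std + clin_effects[1] * stage_std
    sd = c.std()
    c_star = (c - c.mean()) / sd if sd > 0 else np.zeros_like(c)
    return np.column_stack([age_std, stage_std]), c, c_star


def _generate(effect_normal, effect_tumor, deg_lfc, mu, config: SimulationConfig, rng, cohort_id: str) -> PairedStudy:
    """Draw one paired cohort given per-gene effect vectors (length n_genes)."""
    n, g = config.n_patients, config.n_genes
    genes = [f"g{i:04d}" for i in range(g)]
    patients = [f"{cohort_id}_p{i:03d}" for i in range(n)]

    age = rng.uniform(_AGE_LO, _AGE_HI, size=n)
    stage = rng.choice(np.arange(1, 5), size=n, p=_STAGE_PROBS).astype(float)
    clin_std, c_raw, c_star = _standardized_clinical(age, stage, np.asarray(config.clin_effects, float))

    z_normal = rng.standard_normal((n, g))
    z_tumor = rng.standard_normal((n, g))
    lp = c_raw + z_normal @ effect_normal + z_tumor @ effect_tumor
    hazards = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0, size=n) / hazards
    c_rate = _censoring_rate(hazards, config.censor_rate)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-9)

    def tissue_matrix(z, effects, lfc_log):
        log_expr = np.tile(mu, (n, 1)) + config.noise_sd * rng.standard_normal((n, g))
        planted = effects != 0
        # clinical loading scales with the gene's hazard effect: strongly
        # prognostic genes are the ones most tied to stage/age-linked biology
        eff_max = np.abs(effects).max()
        rho = (config.clin_coupling * np.abs(effects[planted]) / eff_max) if eff_max > 0 else 0.0
        mix = np.sqrt(1.0 - np.square(rho))
        log_expr[:, planted] += mix * z[:, planted] + rho * c_star[:, None]
        log_expr += lfc_log[None, :]
        return np.exp(log_expr)

    expr_normal = tissue_matrix(z_normal, effect_normal, np.zeros(g))
    expr_tumor = tissue_matrix(z_tumor, effect_tumor, deg_lfc * np.log(2.0))

    clinical = pd.DataFrame({"age": age, "stage": stage}, index=patients)
    pairing = pd.Series(patients, index=patients, name="patient_id")

    def cohort(expr, tissue):
        return SurvivalCohort(
            expression=pd.DataFrame(expr, index=patients, columns=genes),
            time=time.copy(),
            event=event.copy(),
            clinical=clinical.copy(),
            tissue=tissue,
            cohort_id=cohort_id,
            pairing=pairing.copy(),
        )

    truth = {
        "prognostic_normal": [genes[i] for i in np.flatnonzero(effect_normal)],
        "prognostic_tumor": [genes[i] for i in np.flatnonzero(effect_tumor)],
        "degs": [genes[i] for i in np.flatnonzero(deg_lfc)],
        "effect_normal": effect_normal.copy(),
        "effect_tumor": effect_tumor.copy(),
        "deg_log2fc": deg_lfc.copy(),
        "mu": mu.copy(),
        "clin_effects": tuple(config.clin_effects),
        "linear_predictor": lp.copy(),
    }
    return PairedStudy(tumor=cohort(expr_tumor, "tumor"), normal=cohort(expr_normal, "normal"),
                       pairing=pairing, truth=truth)


def simulate_paired_study(config: SimulationConfig) -> PairedStudy:
    """Generate the discovery cohort described by ``config``.

    Prognostic-normal genes occupy the first gene indices, prognostic-tumor
    genes the next block; DEGs are drawn from the remaining genes unless
    ``deg_on_prognostic`` asks them to coincide with the normal-prognostic
    set (used to study aligned DEG/prognostic planting).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    effect_normal = np.zeros(g)
    effect_tumor = np.zeros(g)
    effect_normal[: config.n_prog_normal] = config.beta_normal
    effect_tumor[config.n_prog_normal : config.n_prog_normal + config.n_prog_tumor] = config.beta_tumor
    deg_lfc = np.zeros(g)
    if config.n_deg:
        if config.deg_on_prognostic:
            idx = np.arange(min(config.n_deg, g))
        else:
            n_planted = config.n_prog_normal + config.n_prog_tumor
            free = np.arange(n_planted, g)
            if len(free) >= config.n_deg:
                idx = free[: config.n_deg]
            else:  # not enough unplanted genes; spill onto planted ones
                idx = np.arange(g)[-config.n_deg :]
        deg_lfc[idx] = config.deg_log2fc
    mu = rng.normal(2.0, 1.0, size=g)
    return _generate(effect_normal, effect_tumor, deg_lfc, mu, config, rng, cohort_id=f"sim{config.seed}")


def simulate_screening_cohort(study: PairedStudy, config: SimulationConfig) -> PairedStudy:
    """Derive an external screening cohort from a discovery study.

    Per-gene normal-tissue effects become
    ``f * b + sqrt(1 - f^2) * permute(b)`` with ``f = shared_normal_fraction``
    (correlation ~f with the source, magnitude preserved); tumor-tissue
    effects use weight ``w = 1 - tumor_divergence`` the same way.  Patients,
    expression and survival are drawn fresh on the same gene universe.
    """
    config.validate()
    if not study.truth or "effect_normal" not in study.truth:
        raise ValueError("source study carries no ground-truth effect vectors")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 815]))

    def remix(effects, weight):
        if weight == 1.0:
            return effects.copy()
        perm = rng.permutation(effects)
        return weight * effects + np.sqrt(1.0 - weight**2) * perm

    eff_n = remix(np.asarray(study.truth["effect_normal"], float), config.shared_normal_fraction)
    eff_t = remix(np.asarray(study.truth["effect_tumor"], float), 1.0 - config.tumor_divergence)
    deg_lfc = np.asarray(study.truth["deg_log2fc"], float)
    mu = np.asarray(study.truth["mu"], float)
    return _generate(eff_n, eff_t, deg_lfc, mu, config, rng, cohort_id=f"screen{config.seed}")


def write_study(study: PairedStudy, out_dir, prefix: str = "study") -> None:
    """Write expression/clinical TSVs plus a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue in ("tumor", "normal"):
        cohort: SurvivalCohort = getattr(study, tissue)
        write_expression(cohort.expression, out / f"{prefix}_{tissue}_expression.tsv")
        clin = cohort.clinical.copy()
        clin.insert(0, "patient_id", cohort.sample_ids)
        clin["time"] = cohort.time
        clin["event"] = cohort.event
        clin["tissue"] = tissue
        clin.to_csv(out / f"{prefix}_{tissue}_clinical.tsv", sep="\t", index=False)
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in study.truth.items()}
    with open(out / f"{prefix}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
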