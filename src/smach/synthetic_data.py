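"""Synthetic cohort and animal-study generators with recorded ground truth.

The cohort generator emulates a pregnancy-cohort biomonitoring table:
correlated lognormal urinary analyte concentrations, a lognormal creatinine,
normally distributed covariates (child age at outcome assessment, weight
percentile, gestational week at sampling), and a continuous outcome
(anogenital distance, mm) generated from a weighted quantile index so that
the WQS estimand is well defined:

    AGD = mu0 + beta1 * sum_j w*_j q_j + covariate effects + noise.

The litter generator emulates a developmental toxicity study: dams nested in
dose groups, pups nested in dams, and a quadratic mean response on the
x = log10(dose+1) scale with a random litter intercept.

Every generated table carries a ``truth`` record sufficient to score the
downstream estimates (weights, index effect, dose-response coefficients,
benchmark dose) for bias.  All randomness flows through one seeded
generator; identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import _decline_root, dose_scale
from .wqs import quantile_scores

__all__ = [
    "CohortGenConfig",
    "LitterGenConfig",
    "SyntheticCohort",
    "SyntheticLitters",
    "generate_cohort",
    "generate_litters",
    "generate_reference_fixture",
]

#: Default urinary analytes: ten phthalate metabolites plus two phenols.
DEFAULT_COMPONENTS: tuple[str, ...] = (
    "mep", "mbp", "mbzp", "mehp", "mehhp", "meohp", "mecpp",
    "mhinp", "moinp", "mciop", "bpa", "triclosan",
)

#: Plausible urinary geometric means (µg/L) for a European pregnancy cohort.
DEFAULT_LOG_GM: dict[str, float] = {
    "mep": float(np.log(60.0)),
    "mbp": float(np.log(65.0)),
    "mbzp": float(np.log(15.0)),
    "mehp": float(np.log(2.7)),
    "mehhp": float(np.log(17.0)),
    "meohp": float(np.log(12.0)),
    "mecpp": float(np.log(15.0)),
    "mhinp": float(np.log(7.0)),
    "moinp": float(np.log(3.0)),
    "mciop": float(np.log(9.0)),
    "bpa": float(np.log(1.5)),
    "triclosan": float(np.log(2.0)),
}

#: Default planted mixture weights: concentrated on the di-isononyl and
#: butyl-benzyl phthalate metabolites, echoing the weight pattern reported
#: for shortened anogenital distance in cohort analyses.
DEFAULT_TRUE_WEIGHTS: dict[str, float] = {
    "mep": 0.04, "mbp": 0.09, "mbzp": 0.29, "mehp": 0.08,
    "mehhp": 0.01, "meohp": 0.005, "mecpp": 0.01,
    "mhinp": 0.30, "moinp": 0.12, "mciop": 0.04,
    "bpa": 0.005, "triclosan": 0.01,
}


@dataclass
class CohortGenConfig:
    """Study conditions for the synthetic biomonitoring cohort.

    Exposures are lognormal with an exchangeable pairwise correlation on the
    log scale; the outcome anchors (mean 41.4 mm, SD 6.1 mm) and covariate
    distributions (age ~ N(21, 1.6^2) months, weight percentile ~ N(56, 27^2),
    gestational week ~ N(10, 2.3^2), creatinine median 9.8 mmol/L) mirror a
    reported pregnancy-cohort summary.  The residual outcome noise is chosen
    so the marginal outcome SD matches ``outcome_sd``.
    """

    n_subjects: int = 500
    components: tuple[str, ...] = DEFAULT_COMPONENTS
    log_gm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_GM))
    log_sd: float = 0.9
    correlation: float = 0.3
    creatinine_median: float = 9.8
    creatinine_log_sd: float = 0.45
    true_weights: Mapping[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_TRUE_WEIGHTS)
    )
    beta1: float = -1.6
    outcome_mean: float = 41.4
    outcome_sd: float = 6.1
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age_months": 0.3, "weight_pct": 0.02, "gest_week": -0.1}
    )
    n_quantiles: int = 4
    outcome_on_quantiles: bool = True
    seed: int = 0

    def weight_vector(self) -> np.ndarray:
        if self.true_weights is None:
            return np.zeros(len(self.components))
        w = np.array([self.true_weights.get(c, 0.0) for c in self.components])
        if np.any(w < 0):
            raise ValueError("true weights must be non-negative")
        tot = w.sum()
        if self.beta1 != 0 and abs(tot - 1.0) > 1e-9:
            raise ValueError("true weights must sum to 1")
        return w


@dataclass
class SyntheticCohort:
    table: pd.DataFrame
    truth: dict


@dataclass
class LitterGenConfig:
    """Study conditions for the synthetic litter-clustered animal study.

    Defaults follow the tested design: dose groups 0 / 0.5 / 10 / 100 times
    the 1X anchor, at least four dams per dose, a gently non-monotone
    quadratic on the log10(dose+1) scale, and litter/pup noise at the scale
    of the observed group SDs.  ``dams_per_dose``, ``pups_per_dam`` and
    ``residual_sd`` accept either a scalar or one value per dose group.
    """

    doses: tuple[float, ...] = (0.0, 0.5, 10.0, 100.0)
    dams_per_dose: int | Sequence[int] = 4
    pups_per_dam: int | Sequence[int] = 5
    beta: tuple[float, float, float] = (1.0, -0.17, 0.07)
    litter_sd: float = 0.03
    residual_sd: float | Sequence[float] = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.doses)) < 3:
            raise ValueError("at least 3 distinct doses are required")
        if self.litter_sd < 0:
            raise ValueError("litter_sd must be non-negative")

    def _per_dose(self, value) -> list:
        if np.isscalar(value):
            return [value] * len(self.doses)
        vals = list(value)
        if len(vals) != len(self.doses):
            raise ValueError("per-dose settings must match the number of doses")
        return vals


@dataclass
class SyntheticLitters:
    table: pd.DataFrame
    truth: dict


def generate_cohort(cfg: CohortGenConfig) -> SyntheticCohort:
    """Draw a complete-case cohort table with recorded generating truth."""
    rng = np.random.default_rng(cfg.seed)
    n, comps = cfg.n_subjects, list(cfg.components)
    p = len(comps)

    rho = cfg.correlation
    if p > 1 and not (-1.0 / (p - 1) < rho < 1.0):
        raise ValueError("exchangeable correlation is not positive definite")
    R = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    L = np.linalg.cholesky(R)

    z = rng.standard_normal((n, p)) @ L.T
    mu = np.array([cfg.log_gm[c] for c in comps])
    conc = np.exp(mu + cfg.log_sd * z)

    creatinine = np.exp(
        np.log(cfg.creatinine_median) + cfg.creatinine_log_sd * rng.standard_normal(n)
    )
    age = 21.0 + 1.6 * rng.standard_normal(n)
    wpct = np.clip(56.0 + 27.0 * rng.standard_normal(n), 0.5, 99.5)
    gweek = np.clip(10.0 + 2.3 * rng.standard_normal(n), 3.0, 27.0)

    w = cfg.weight_vector()
    if cfg.outcome_on_quantiles:
        qm = quantile_scores(pd.DataFrame(conc, columns=comps), cfg.n_quantiles)
        index = qm.scores @ w
    else:
        # robustness variant: index on standardized log concentrations,
        # rescaled to the quantile-score range for a comparable beta1
        zstd = (np.log(conc) - mu) / cfg.log_sd
        index = (zstd - zstd.min(axis=0)).dot(w)

    eff = {"age_months": age, "weight_pct": wpct, "gest_week": gweek}
    cov_term = sum(coef * eff[name] for name, coef in cfg.covariate_effects.items())
    signal = cfg.beta1 * index + cov_term

    explained_var = float(np.var(signal))
    resid_var = max(cfg.outcome_sd ** 2 - explained_var, 0.25)
    mu0 = cfg.outcome_mean - float(np.mean(signal))
    outcome = mu0 + signal + np.sqrt(resid_var) * rng.standard_normal(n)

    table = pd.DataFrame(
        {
            "subject_id": [f"s{i:05d}" for i in range(n)],
            "creatinine_mmol_per_l": creatinine,
            **{c: conc[:, j] for j, c in enumerate(comps)},
            "age_months": age,
            "weight_pct": wpct,
            "gest_week": gweek,
            "agd_mm": outcome,
        }
    )
    truth = {
        "weights": dict(zip(comps, w.tolist())),
        "beta1": cfg.beta1,
        "mu0": mu0,
        "residual_sd": float(np.sqrt(resid_var)),
        "covariate_effects": dict(cfg.covariate_effects),
        "n_quantiles": cfg.n_quantiles,
        "seed": cfg.seed,
    }
    return SyntheticCohort(table=table, truth=truth)


def generate_litters(cfg: LitterGenConfig) -> SyntheticLitters:
    """Draw pup-level responses from the quadratic mixed model."""
    rng = np.random.default_rng(cfg.seed)
    dams = cfg._per_dose(cfg.dams_per_dose)
    pups = cfg._per_dose(cfg.pups_per_dam)
    res_sd = cfg._per_dose(cfg.residual_sd)
    b0, b1, b2 = cfg.beta

    rows = []
    litter_counter = 0
    for dose, n_dam, n_pup, sd in zip(cfg.doses, dams, pups, res_sd):
        x = float(dose_scale(dose))
        mean = b0 + b1 * x + b2 * x * x
        for _ in range(int(n_dam)):
            litter_counter += 1
            u = cfg.litter_sd * rng.standard_normal()
            eps = sd * rng.standard_normal(int(n_pup))
            for e in eps:
                rows.append(
                    {
                        "litter_id": f"dam{litter_counter:03d}",
                        "dose_multiple": dose,
                        "response": mean + u + float(e),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "beta": list(cfg.beta),
        "litter_sd": cfg.litter_sd,
        "residual_sd": res_sd,
        "seed": cfg.seed,
    }
    try:
        truth["bmd_5pct"] = _decline_root(np.array(cfg.beta), 0.05)
        truth["ed_8pct"] = _decline_root(np.array(cfg.beta), 0.08)
        truth["radius"] = truth["ed_8pct"] - truth["bmd_5pct"]
    except ValueError:
        pass  # flat or increasing truth: no benchmark dose
    return SyntheticLitters(table=table, truth=truth)


def generate_reference_fixture(seed: int = 0) -> dict:
    """A small end-to-end fixture: cohort, litters, and default constants.

    Returns a dict with a 200-subject cohort, a 16-dam animal study, the
    default dosimetry constants and the default guideline table, plus both
    generating-truth records.
    """
    from .constants import default_be_table, default_constants

    cohort = generate_cohort(CohortGenConfig(n_subjects=200, seed=seed))
    litters = generate_litters(LitterGenConfig(dams_per_dose=4, seed=seed + 1))
    return {
        "cohort": cohort.table,
        "cohort_truth": cohort.truth,
        "litters": litters.table,
        "litters_truth": litters.truth,
        "constants": default_constants(),
        "be_table": default_be_table(),
    }
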