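"""End-to-end orchestration of the four-step whole-mixture assessment.

Step 1 identifies "bad actor" analytes by weighted quantile sum regression;
Step 2 back-calculates daily intakes and serum levels and defines the
reference mixture from geometric-mean anchors; Step 3 fits the
litter-clustered quadratic dose-response model and derives the benchmark
dose, its uncertainty, and the similarity radius; Step 4 scores every
subject for sufficient similarity and the similar mixture risk indicator,
with the dose-addition hazard index and single-compound guideline
exceedances as comparators.

Each step writes diffable intermediate artifacts (JSON for model objects,
CSV for per-subject tables) when an output directory is given, so any step
can be re-run from its predecessor's files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (
    BeTable,
    ConstantsConfig,
    default_be_table,
    default_constants,
    load_be_table,
    load_constants,
)
from .dose_response import back_transform, bmd_analysis, dunnett_anova
from .dosimetry import cohort_serum, reference_mixture_from_cohort
from .similarity import (
    ReferenceMixture,
    cohort_summary,
    hazard_index_cohort,
    score_cohort,
)
from .wqs import WqsConfig, fit_wqs, quantile_scores, select_bad_actors

__all__ = [
    "PipelineSettings",
    "RunReport",
    "run_pipeline",
    "run_from_config",
    "single_compound_exceedance",
]

LN10 = math.log(10.0)

#: Phenols measured in the cohort but not carried into the reference mixture
#: (no serum mixture support in the assessment design).
DEFAULT_EXCLUDED_PARENTS: tuple[str, ...] = ("bpa", "triclosan")


@dataclass
class PipelineSettings:
    """Tunable settings for one pipeline run."""

    outcome: str = "agd_mm"
    components: Sequence[str] | None = None  # default: all metabolite columns
    covariates: Sequence[str] = ("age_months", "weight_pct", "gest_week")
    direction: str = "negative"
    n_quantiles: int = 4
    n_bootstrap: int = 100
    split_fraction: float = 0.4
    bmr: float = 0.05
    ed_decline: float = 0.08
    excluded_parents: Sequence[str] = DEFAULT_EXCLUDED_PARENTS
    forced_mixture_parents: Sequence[str] | None = None
    normalize_smri: bool = False
    seed: int = 0


@dataclass
class RunReport:
    """Headline results of a full run; percentages are on the 0-100 scale."""

    bad_actor_metabolites: tuple[str, ...]
    mixture_parents: tuple[str, ...]
    mixture_proportions: dict
    anchor_total_mol_per_l: float
    wqs_beta1: float
    wqs_se: float
    wqs_p_value: float
    wqs_weights: dict
    bmd: float
    bmd_se: float
    bmdl: float
    ed8: float
    radius: float
    bmd_multiple_of_1x: float
    ed8_multiple_of_1x: float
    pct_similar: float
    pct_smri_gt1_of_similar: float
    pct_smri_gt1_of_all: float
    pct_hi_gt1: float
    pct_above_be: dict
    n_subjects_scored: int
    n_subjects_unscored: int
    provenance: dict = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def single_compound_exceedance(cohort: pd.DataFrame, be: BeTable) -> dict[str, float]:
    """Fraction of subjects strictly above each guideline value.

    Summed metabolite bases are aggregated before comparison; a subject
    exactly at the guideline does not exceed it.
    """
    out = {}
    for entry in be:
        missing = [m for m in entry.basis if m not in cohort.columns]
        if missing:
            raise KeyError(
                f"cohort table missing columns {missing} for guideline "
                f"{entry.chemical!r}"
            )
        conc = cohort[list(entry.basis)].sum(axis=1).to_numpy(dtype=float)
        out[entry.chemical] = float((conc > entry.be_ug_per_l).mean())
    return out


def _metabolite_columns(cohort: pd.DataFrame, constants: ConstantsConfig) -> list[str]:
    known = constants.metabolite_index()
    return [c for c in cohort.columns if c in known]


def run_pipeline(
    cohort: pd.DataFrame,
    animals: pd.DataFrame,
    constants: ConstantsConfig | None = None,
    be_table: BeTable | None = None,
    settings: PipelineSettings | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Execute Steps 1-4 and return the headline report.

    Aborts with a step-labelled error on any failure.  When ``outdir`` is
    given, per-step artifacts (weights, mixture definition, dose-response
    summary, per-subject scores) and the final report are written there.
    """
    constants = constants or default_constants()
    be_table = be_table or default_be_table()
    settings = settings or PipelineSettings()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- Step 1: bad actors via WQS --------------------------------------
    try:
        comp_cols = (
            list(settings.components)
            if settings.components is not None
            else _metabolite_columns(cohort, constants)
        )
        if not comp_cols:
            raise ValueError("no metabolite columns found in the cohort table")
        qm = quantile_scores(cohort[comp_cols], settings.n_quantiles)
        covs = cohort[list(settings.covariates)] if settings.covariates else None
        wqs_res = fit_wqs(
            qm,
            cohort[settings.outcome],
            covs,
            WqsConfig(
                direction=settings.direction,
                n_bootstrap=settings.n_bootstrap,
                split_fraction=settings.split_fraction,
                n_quantiles=settings.n_quantiles,
                seed=settings.seed,
            ),
        )
        bad = select_bad_actors(wqs_res)
    except Exception as exc:
        raise RuntimeError(f"step 1 (WQS) failed: {exc}") from exc
    if out is not None:
        wqs_res.weights.to_csv(out / "step1_weights.csv")
        (out / "step1_wqs.json").write_text(json.dumps(_jsonable({
            "beta1": wqs_res.beta1, "se": wqs_res.se_beta1,
            "p_value": wqs_res.p_value, "threshold": bad.threshold,
            "bad_actors": list(bad.components),
            "small_sample": wqs_res.small_sample,
        }), indent=2))

    # ---- Step 2: reference mixture from dosimetry ------------------------
    try:
        if settings.forced_mixture_parents is not None:
            parents = list(settings.forced_mixture_parents)
        else:
            met_index = constants.metabolite_index()
            parents = []
            for m in bad.components:
                p = met_index[m].parent
                if p not in parents and p not in settings.excluded_parents:
                    parents.append(p)
        if not parents:
            raise ValueError("no mixture parents selected from the bad actors")
        mixture = reference_mixture_from_cohort(cohort, constants, parents)
        serum = cohort_serum(cohort, constants, parents)
    except Exception as exc:
        raise RuntimeError(f"step 2 (dosimetry) failed: {exc}") from exc
    if out is not None:
        serum.to_csv(out / "step2_serum_mol_per_l.csv")
        (out / "step2_mixture.json").write_text(json.dumps(_jsonable({
            "components": list(mixture.components),
            "proportions": list(mixture.proportions),
            "anchor_1x_mol_per_l": list(mixture.anchor_1x),
            "anchor_total_mol_per_l": mixture.anchor_total,
        }), indent=2))

    # ---- Step 3: dose-response and benchmark dose ------------------------
    try:
        dunnett = dunnett_anova(animals)
        fit, bmd_res = bmd_analysis(
            animals, bmr=settings.bmr, ed_decline=settings.ed_decline
        )
    except Exception as exc:
        raise RuntimeError(f"step 3 (dose-response) failed: {exc}") from exc
    if out is not None:
        dunnett.to_csv(out / "step3_dunnett.csv")
        (out / "step3_bmd.json").write_text(json.dumps(_jsonable({
            "beta": fit.beta, "vcov": fit.vcov,
            "litter_variance": fit.litter_variance,
            "residual_variance": fit.residual_variance,
            "bmd": bmd_res.bmd, "se_bmd": bmd_res.se_bmd,
            "bmdl": bmd_res.bmdl, "ed8": bmd_res.ed8,
            "radius": bmd_res.radius, "df": bmd_res.df,
            "bmd_multiple_of_1x": bmd_res.bmd_multiple,
            "ed8_multiple_of_1x": bmd_res.ed8_multiple,
        }), indent=2))

    # ---- Step 4: similarity, SMRI, HI ------------------------------------
    try:
        # benchmark dose on the serum concentration scale: the x-scale BMD is
        # log10(multiple + 1), so T_r = (10^bmd - 1) * anchor_total mol/L and
        # SE follows by the delta method through the same transform.
        t_r = back_transform(bmd_res.bmd) * mixture.anchor_total
        se_tr = LN10 * (10.0 ** bmd_res.bmd) * bmd_res.se_bmd * mixture.anchor_total
        ref = ReferenceMixture.from_mixture(mixture, t_r=t_r, se_tr=se_tr, df=fit.df)
        radius_conc = (
            back_transform(bmd_res.ed8) - back_transform(bmd_res.bmd)
        ) * mixture.anchor_total
        scores = score_cohort(
            serum, ref, radius_conc, normalize_smri=settings.normalize_smri
        )
        his = hazard_index_cohort(cohort.set_index("subject_id"), be_table)
        summary = cohort_summary(scores, his)
        exceed = single_compound_exceedance(cohort, be_table)
    except Exception as exc:
        raise RuntimeError(f"step 4 (similarity) failed: {exc}") from exc
    if out is not None:
        merged = scores.copy()
        merged["hazard_index"] = his.to_numpy()
        merged.to_csv(out / "step4_scores.csv")
        (out / "step4_summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2)
        )

    settings_blob = json.dumps(_jsonable(asdict(settings)), sort_keys=True)
    provenance = {
        "smach_version": __version__,
        "seed": settings.seed,
        "config_sha256": hashlib.sha256(settings_blob.encode()).hexdigest(),
        "constants_version": constants.version,
        "be_version": be_table.version,
        "constants_tk": asdict(constants.tk),
        "t_r_mol_per_l": t_r,
        "se_tr_mol_per_l": se_tr,
        "radius_mol_per_l": radius_conc,
    }
    report = RunReport(
        bad_actor_metabolites=tuple(bad.components),
        mixture_parents=tuple(mixture.components),
        mixture_proportions=dict(zip(mixture.components, mixture.proportions)),
        anchor_total_mol_per_l=mixture.anchor_total,
        wqs_beta1=wqs_res.beta1,
        wqs_se=wqs_res.se_beta1,
        wqs_p_value=wqs_res.p_value,
        wqs_weights=wqs_res.weights.to_dict(),
        bmd=bmd_res.bmd,
        bmd_se=bmd_res.se_bmd,
        bmdl=bmd_res.bmdl,
        ed8=bmd_res.ed8,
        radius=bmd_res.radius,
        bmd_multiple_of_1x=bmd_res.bmd_multiple,
        ed8_multiple_of_1x=bmd_res.ed8_multiple,
        pct_similar=100.0 * summary["fraction_similar"],
        pct_smri_gt1_of_similar=100.0 * summary["fraction_smri_gt1_of_similar"],
        pct_smri_gt1_of_all=100.0 * summary["fraction_smri_gt1_of_all"],
        pct_hi_gt1=100.0 * summary["fraction_hi_gt1"],
        pct_above_be={k: 100.0 * v for k, v in exceed.items()},
        n_subjects_scored=summary["n_scored"],
        n_subjects_unscored=summary["n_unscored"],
        provenance=provenance,
    )
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(_jsonable(asdict(report)), indent=2)
        )
    return report


def run_from_config(config_path: str | Path) -> RunReport:
    """Run the pipeline from a YAML configuration file.

    Required keys: ``cohort`` and ``animals`` (CSV paths).  Optional:
    ``constants`` and ``be_values`` (YAML paths; packaged defaults are used
    when absent), ``outdir``, and any :class:`PipelineSettings` field under
    ``settings``.
    """
    cfg_path = Path(config_path)
    doc = yaml.safe_load(cfg_path.read_text())
    base = cfg_path.parent

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    for key in ("cohort", "animals"):
        if key not in doc:
            raise KeyError(f"pipeline config is missing required key {key!r}")
        if not _resolve(doc[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {_resolve(doc[key])}")
    cohort = pd.read_csv(_resolve(doc["cohort"]))
    animals = pd.read_csv(_resolve(doc["animals"]))
    constants = (
        load_constants(_resolve(doc["constants"])) if "constants" in doc
        else default_constants()
    )
    be_table = (
        load_be_table(_resolve(doc["be_values"])) if "be_values" in doc
        else default_be_table()
    )
    settings = PipelineSettings(**doc.get("settings", {}))
    outdir = _resolve(doc["outdir"]) if "outdir" in doc else None
    return run_pipeline(cohort, animals, constants, be_table, settings, outdir)
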