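"""Sufficient-similarity scoring, SMRI, and the hazard-index comparator.

A subject's mixture (component exposures E_j, proportions a_ij = E_j / sum E)
is compared to the experimentally tested reference mixture (proportions a_rj,
benchmark dose T_r in total-dose units) through a scaled Euclidean distance

    d_i = T_r * sqrt( sum_j (a_ij - a_rj)^2 ),

whose one-sided 95% upper limit uses the uncertainty of T_r,

    UL_i = d_i + t(0.95, df) * SE(T_r) * sqrt( sum_j (a_ij - a_rj)^2 ).

The subject is "sufficiently similar" when UL_i < R, the similarity-region
radius from the dose-response stage.  For similar subjects the similar
mixture risk indicator sums exposure over the per-component mixture
reference values mRV_j = a_rj * T_r,

    SMRI_i = sum_j E_j / mRV_j,

with values above 1 flagged as of concern.  The dose-addition comparator is
the hazard index, HI_i = sum_j conc_j / BE_j over published guideline values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BeTable
from .dosimetry import MixtureDefinition

__all__ = [
    "ReferenceMixture",
    "SubjectMixture",
    "SimilarityDecision",
    "SmriValue",
    "mixture_distance",
    "distance_upper_limit",
    "decide_similarity",
    "smri",
    "hazard_index",
    "score_cohort",
    "cohort_summary",
]


@dataclass(frozen=True)
class ReferenceMixture:
    """Reference proportions with the benchmark dose in total-dose units."""

    components: tuple[str, ...]
    proportions: tuple[float, ...]
    t_r: float
    se_tr: float
    df: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("reference proportions must lie on the simplex")
        if self.t_r <= 0:
            raise ValueError("t_r must be strictly positive")
        if self.se_tr < 0:
            raise ValueError("se_tr must be non-negative")

    @classmethod
    def from_mixture(
        cls,
        mixture: MixtureDefinition,
        t_r: float,
        se_tr: float,
        df: int,
    ) -> "ReferenceMixture":
        return cls(
            components=mixture.components,
            proportions=mixture.proportions,
            t_r=t_r,
            se_tr=se_tr,
            df=df,
        )


@dataclass(frozen=True)
class SubjectMixture:
    """One subject's component exposures in the reference's units."""

    subject_id: str
    components: tuple[str, ...]
    exposures: tuple[float, ...]  # E_j, same units as t_r * a_rj

    def __post_init__(self) -> None:
        e = np.asarray(self.exposures)
        if np.any(e < 0):
            raise ValueError(f"negative exposure for subject {self.subject_id}")

    @property
    def total(self) -> float:
        return float(sum(self.exposures))

    @property
    def proportions(self) -> np.ndarray:
        tot = self.total
        if tot <= 0:
            raise ValueError(
                f"subject {self.subject_id} has all-zero exposures; "
                "mixture proportions are undefined"
            )
        return np.asarray(self.exposures) / tot


@dataclass(frozen=True)
class SimilarityDecision:
    subject_id: str
    d_hat: float
    ul: float
    radius: float
    similar: bool


@dataclass(frozen=True)
class SmriValue:
    subject_id: str
    smri: float

    @property
    def exceeds_one(self) -> bool:
        return self.smri > 1.0


def _check_components(subject: SubjectMixture, ref: ReferenceMixture) -> None:
    if subject.components != ref.components:
        raise ValueError(
            f"component mismatch: subject has {subject.components}, "
            f"reference has {ref.components}"
        )


def mixture_distance(subject: SubjectMixture, ref: ReferenceMixture) -> float:
    """Scaled Euclidean distance between subject and reference proportions."""
    _check_components(subject, ref)
    diff = subject.proportions - np.asarray(ref.proportions)
    return float(ref.t_r * np.sqrt(diff @ diff))


def distance_upper_limit(
    d_hat: float,
    subject: SubjectMixture,
    ref: ReferenceMixture,
) -> float:
    """One-sided 95% upper confidence limit on the distance."""
    _check_components(subject, ref)
    if ref.df <= 0:
        raise ValueError("df must be positive")
    diff = subject.proportions - np.asarray(ref.proportions)
    return float(d_hat + stats.t.ppf(0.95, ref.df) * ref.se_tr * np.sqrt(diff @ diff))


def decide_similarity(
    subject_id: str,
    d_hat: float,
    ul: float,
    radius: float,
) -> SimilarityDecision:
    """Sufficient similarity holds when UL < R (strict)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return SimilarityDecision(
        subject_id=subject_id,
        d_hat=d_hat,
        ul=ul,
        radius=radius,
        similar=bool(ul < radius),
    )


def smri(subject: SubjectMixture, ref: ReferenceMixture, normalize: bool = False) -> SmriValue:
    """Similar mixture risk indicator: sum of E_j / (a_rj * T_r).

    With the definition taken verbatim, a subject exactly at the reference
    proportions with total exposure T_r scores the number of components (each
    quotient is 1); ``normalize=True`` divides by the component count so that
    this canonical subject scores 1 instead — an extension, off by default.
    """
    _check_components(subject, ref)
    e = np.asarray(subject.exposures, dtype=float)
    a = np.asarray(ref.proportions, dtype=float)
    active_undefined = (a == 0) & (e > 0)
    if np.any(active_undefined):
        bad = [c for c, flag in zip(ref.components, active_undefined) if flag]
        raise ValueError(
            f"SMRI undefined: zero reference proportion with nonzero exposure "
            f"for {bad} (subject {subject.subject_id})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(e > 0, e / (a * ref.t_r), 0.0)
    value = float(terms.sum())
    if normalize:
        value /= len(ref.components)
    return SmriValue(subject_id=subject.subject_id, smri=value)


def hazard_index(
    concentrations: Mapping[str, float],
    be: BeTable,
) -> float:
    """Dose-addition hazard index: sum of concentration / guideline quotients.

    ``concentrations`` is keyed by the guideline's metabolite basis, already
    aggregated (µg/L): for a summed basis pass the summed concentration under
    the chemical's name or any of its basis names.
    """
    total = 0.0
    for entry in be:
        key_candidates = (entry.chemical, *entry.basis)
        found = [k for k in key_candidates if k in concentrations]
        if not found:
            raise KeyError(
                f"no concentration provided for guideline basis of "
                f"{entry.chemical!r} (expected one of {key_candidates})"
            )
        total += concentrations[found[0]] / entry.be_ug_per_l
    return float(total)


def hazard_index_cohort(cohort: pd.DataFrame, be: BeTable) -> pd.Series:
    """Per-subject hazard index from a cohort table with metabolite columns.

    Summed bases (e.g., a guideline on the sum of four metabolites) are
    aggregated from the individual metabolite columns.
    """
    hi = np.zeros(len(cohort))
    for entry in be:
        missing = [m for m in entry.basis if m not in cohort.columns]
        if missing:
            raise KeyError(
                f"cohort table missing columns {missing} for guideline "
                f"{entry.chemical!r}"
            )
        conc = cohort[list(entry.basis)].sum(axis=1).to_numpy(dtype=float)
        hi = hi + conc / entry.be_ug_per_l
    return pd.Series(hi, index=cohort.index, name="hazard_index")


def score_cohort(
    exposures: pd.DataFrame,
    ref: ReferenceMixture,
    radius: float,
    normalize_smri: bool = False,
) -> pd.DataFrame:
    """Distance, upper limit, similarity flag and SMRI for every subject.

    ``exposures`` is indexed by subject with one column per reference
    component (units of t_r).  Subjects with all-zero exposures have no
    defined mixture proportions; they are returned with NaN scores and
    ``scored=False`` so they can be reported separately.
    """
    cols = list(ref.components)
    missing = [c for c in cols if c not in exposures.columns]
    if missing:
        raise KeyError(f"exposure table missing components: {missing}")
    rows = []
    for sid, row in exposures[cols].iterrows():
        subj = SubjectMixture(
            subject_id=str(sid),
            components=ref.components,
            exposures=tuple(float(v) for v in row),
        )
        if subj.total <= 0:
            rows.append({"subject_id": str(sid), "d_hat": np.nan, "ul": np.nan,
                         "similar": False, "smri": np.nan, "scored": False})
            continue
        d = mixture_distance(subj, ref)
        ul = distance_upper_limit(d, subj, ref)
        dec = decide_similarity(str(sid), d, ul, radius)
        rows.append({
            "subject_id": str(sid),
            "d_hat": d,
            "ul": ul,
            "similar": dec.similar,
            "smri": smri(subj, ref, normalize=normalize_smri).smri,
            "scored": True,
        })
    return pd.DataFrame(rows).set_index("subject_id")


def cohort_summary(
    scores: pd.DataFrame,
    his: pd.Series | Sequence[float] | None = None,
    n_bins: int = 30,
) -> dict:
    """Aggregate per-subject similarity/SMRI/HI results into headline fractions.

    Returns fractions of scored subjects that are sufficiently similar, the
    fraction of similar subjects with SMRI > 1, the fraction of all scored
    subjects with SMRI > 1, the fraction with HI > 1 (when provided), and
    histogram-ready bin edges/counts for the SMRI and HI distributions.
    """
    if len(scores) == 0:
        raise ValueError("empty cohort: nothing to summarize")
    scored = scores[scores["scored"]] if "scored" in scores.columns else scores
    n = len(scored)
    if n == 0:
        raise ValueError("no subject had a defined mixture; nothing to summarize")
    similar = scored["similar"].to_numpy(dtype=bool)
    smris = scored["smri"].to_numpy(dtype=float)
    frac_similar = float(similar.mean())
    exceed_all = float((smris > 1.0).mean())
    if similar.any():
        exceed_similar = float((smris[similar] > 1.0).mean())
    else:
        exceed_similar = float("nan")
    out = {
        "n_scored": n,
        "n_unscored": int(len(scores) - n),
        "fraction_similar": frac_similar,
        "fraction_smri_gt1_of_similar": exceed_similar,
        "fraction_smri_gt1_of_all": exceed_all,
    }
    counts, edges = np.histogram(smris[np.isfinite(smris)], bins=n_bins)
    out["smri_hist"] = {"counts": counts.tolist(), "edges": edges.tolist()}
    if his is not None:
        hi_arr = np.asarray(his, dtype=float)
        out["fraction_hi_gt1"] = float((hi_arr > 1.0).mean())
        counts, edges = np.histogram(hi_arr[np.isfinite(hi_arr)], bins=n_bins)
        out["hi_hist"] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return out


__all__.append("hazard_index_cohort")
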