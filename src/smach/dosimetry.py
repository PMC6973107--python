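"""Urinary-biomarker dosimetry: daily intake, serum levels, mixing proportions.

The chain implemented here converts creatinine-adjusted urinary metabolite
concentrations into a molar daily intake (DI) of the parent diester,

    DI [mol/kg bw/day] = UE [mol/g crt] * CE [g crt/kg bw/day] / F_UE,

where UE sums (conc_metabolite [g/L] / MW_metabolite) over the parent's
measured metabolites and divides by urinary creatinine in g/L, and F_UE is
the molar excretion fraction.  Intake maps to a steady-state blood plasma
concentration through a one-compartment toxicokinetic model,

    Cp [mol/L] = E * t_half / (0.693 * V_d),       E = 0.693 / t_half * V_d * Cp,

and geometric-mean serum levels across a cohort define the reference-mixture
mixing proportions (the "1X" anchor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import CREATININE_MW, ConstantsConfig, ParentSpec, TKParams

__all__ = [
    "UrineSample",
    "MixtureDefinition",
    "creatinine_g_per_l",
    "daily_intake",
    "serum_from_intake",
    "intake_from_serum",
    "geometric_mean",
    "mixing_proportions",
    "substitute_below_lod",
    "cohort_daily_intake",
    "cohort_serum",
]

#: First-order elimination constant numerator as conventionally rounded (ln 2).
LN2_APPROX = 0.693


@dataclass(frozen=True)
class UrineSample:
    """One subject's urine measurements.

    concentrations are µg/L keyed by metabolite name; creatinine is mmol/L.
    """

    subject_id: str
    creatinine: float  # mmol/L
    concentrations: Mapping[str, float]  # µg/L

    def __post_init__(self) -> None:
        if self.creatinine <= 0:
            raise ValueError(f"creatinine must be > 0 (subject {self.subject_id})")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")


@dataclass(frozen=True)
class MixtureDefinition:
    """A reference mixture: ordered components, simplex proportions, 1X anchor.

    ``anchor_1x`` holds the per-component geometric-mean serum levels (mol/L)
    whose sum is the total-dose anchor defining "1X".  Proportions are carried
    at full precision; round only for display.
    """

    components: tuple[str, ...]
    proportions: tuple[float, ...]
    anchor_1x: tuple[float, ...]
    anchor_total: float

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be non-negative and sum to 1")
        if abs(sum(self.anchor_1x) - self.anchor_total) > 1e-9 * max(self.anchor_total, 1e-300):
            raise ValueError("anchor total must equal the sum of component anchors")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.components), name="proportion")


def creatinine_g_per_l(creatinine_mmol_per_l: float) -> float:
    """Convert urinary creatinine from mmol/L to g/L (molar mass 113.12 g/mol)."""
    if creatinine_mmol_per_l <= 0:
        raise ValueError("creatinine must be strictly positive")
    return creatinine_mmol_per_l * CREATININE_MW / 1000.0


def daily_intake(sample: UrineSample, parent: ParentSpec, tk: TKParams) -> float:
    """Molar daily intake (mol/kg bw/day) of ``parent`` back-calculated from urine.

    Sums molar excretion over all of the parent's metabolites (they share one
    F_UE), creatinine-adjusts, scales by the creatinine excretion rate and
    divides by the excretion fraction.  Urinary concentrations are µg/L and
    converted to g/L internally.

    Raises
    ------
    KeyError
        If any of the parent's metabolites is missing from the sample; a
        multi-metabolite intake with a silently dropped metabolite would be
        biased low, so this fails loudly.
    """
    creat = creatinine_g_per_l(sample.creatinine)
    ue = 0.0  # mol per g creatinine
    for met in parent.metabolites:
        if met.name not in sample.concentrations:
            raise KeyError(
                f"metabolite {met.name!r} required for parent {parent.name!r} "
                f"missing from sample {sample.subject_id!r}"
            )
        conc_g_per_l = sample.concentrations[met.name] * 1e-6
        ue += (conc_g_per_l / met.mw_metabolite) / creat
    return ue * tk.ce / parent.f_ue


def serum_from_intake(e: float, tk: TKParams) -> float:
    """Steady-state plasma concentration (mol/L) for intake ``e`` (mol/kg bw/day)."""
    if e < 0:
        raise ValueError("intake must be non-negative")
    return e * tk.t_half / (LN2_APPROX * tk.v_d)


def intake_from_serum(cp: float, tk: TKParams) -> float:
    """Daily intake (mol/kg bw/day) producing plasma concentration ``cp`` (mol/L)."""
    if cp < 0:
        raise ValueError("serum concentration must be non-negative")
    return LN2_APPROX / tk.t_half * tk.v_d * cp


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log values)); every value must be strictly positive."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def mixing_proportions(anchors: Mapping[str, float]) -> MixtureDefinition:
    """Build a reference mixture from per-component serum anchors (mol/L).

    proportion_j = anchor_j / sum(anchors); the result is renormalized so the
    proportions sum to 1 exactly.  Scale-invariant: multiplying every anchor
    by a constant leaves the proportions unchanged.
    """
    if not anchors:
        raise ValueError("at least one component anchor is required")
    names = tuple(anchors.keys())
    vals = np.asarray([anchors[n] for n in names], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("anchors must be strictly positive")
    props = vals / vals.sum()
    props = props / props.sum()  # exact renormalization
    return MixtureDefinition(
        components=names,
        proportions=tuple(float(p) for p in props),
        anchor_1x=tuple(float(v) for v in vals),
        anchor_total=float(vals.sum()),
    )


def substitute_below_lod(
    concentrations: pd.DataFrame,
    lod: Mapping[str, float],
    method: str = "sqrt2",
) -> pd.DataFrame:
    """Replace values below the limit of detection, column-wise.

    method: 'sqrt2' -> LOD/sqrt(2) (default), 'half' -> LOD/2, 'lod' -> LOD,
    'drop' -> NaN (row becomes incomplete and is excluded downstream).
    """
    subs = {
        "sqrt2": lambda l: l / np.sqrt(2.0),
        "half": lambda l: l / 2.0,
        "lod": lambda l: l,
        "drop": lambda l: np.nan,
    }
    if method not in subs:
        raise ValueError(f"unknown LOD substitution method {method!r}")
    out = concentrations.copy()
    for col, limit in lod.items():
        if col in out.columns:
            out.loc[out[col] < limit, col] = subs[method](limit)
    return out


def _sample_from_row(row: pd.Series, metabolites: Iterable[str]) -> UrineSample:
    return UrineSample(
        subject_id=str(row["subject_id"]),
        creatinine=float(row["creatinine_mmol_per_l"]),
        concentrations={m: float(row[m]) for m in metabolites},
    )


def cohort_daily_intake(
    cohort: pd.DataFrame,
    constants: ConstantsConfig,
    parents: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-subject daily intake (mol/kg bw/day) for each requested parent.

    ``cohort`` needs columns subject_id, creatinine_mmol_per_l and one column
    per metabolite (µg/L).  Returns a DataFrame indexed by subject_id with one
    column per parent.
    """
    names = list(parents) if parents is not None else list(constants.parents)
    missing = [p for p in names if p not in constants.parents]
    if missing:
        raise KeyError(f"parents not in constants config: {missing}")
    needed = [m.name for p in names for m in constants.parents[p].metabolites]
    absent = [m for m in needed if m not in cohort.columns]
    if absent:
        raise KeyError(f"cohort table missing metabolite columns: {absent}")
    out = {}
    for _, row in cohort.iterrows():
        sample = _sample_from_row(row, needed)
        out[sample.subject_id] = {
            p: daily_intake(sample, constants.parents[p], constants.tk) for p in names
        }
    di = pd.DataFrame.from_dict(out, orient="index")[names]
    di.index.name = "subject_id"
    return di


def cohort_serum(
    cohort: pd.DataFrame,
    constants: ConstantsConfig,
    parents: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-subject steady-state serum concentration (mol/L) per parent."""
    di = cohort_daily_intake(cohort, constants, parents)
    factor = constants.tk.t_half / (LN2_APPROX * constants.tk.v_d)
    return di * factor


def reference_mixture_from_cohort(
    cohort: pd.DataFrame,
    constants: ConstantsConfig,
    parents: Iterable[str],
) -> MixtureDefinition:
    """Geometric-mean serum anchors over the cohort -> reference mixture.

    Subjects with a zero intake for any component are excluded from that
    component's geometric mean (a zero has no logarithm); a warning reports
    how many were dropped.
    """
    serum = cohort_serum(cohort, constants, parents)
    anchors = {}
    for p in serum.columns:
        vals = serum[p].to_numpy()
        pos = vals[vals > 0]
        if pos.size < vals.size:
            warnings.warn(
                f"{vals.size - pos.size} zero serum values for {p} excluded "
                "from the geometric mean",
                stacklevel=2,
            )
        anchors[p] = geometric_mean(pos)
    return mixing_proportions(anchors)


# re-exported for pipeline convenience
__all__.append("reference_mixture_from_cohort")
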