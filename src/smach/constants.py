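"""Constant tables and configuration objects for the dosimetry chain.

Molecular weights, urinary excretion factors and toxicokinetic parameters are
shipped as a versioned YAML file (``data/constants.yaml``); biomonitoring
equivalent (BE/HBM) guideline values live in ``data/be_values.yaml``.  Both can
be replaced by user files of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CREATININE_MW",
    "MetaboliteSpec",
    "ParentSpec",
    "TKParams",
    "ConstantsConfig",
    "BeEntry",
    "BeTable",
    "load_constants",
    "load_be_table",
    "default_constants",
    "default_be_table",
]

#: Molar mass of creatinine, g/mol.  Fixed, not configurable.
CREATININE_MW = 113.12


@dataclass(frozen=True)
class MetaboliteSpec:
    """A urinary metabolite measured for one parent diester."""

    name: str
    parent: str
    mw_metabolite: float  # g/mol

    def __post_init__(self) -> None:
        if self.mw_metabolite <= 0:
            raise ValueError(f"mw_metabolite must be > 0 for {self.name}")


@dataclass(frozen=True)
class ParentSpec:
    """A parent compound with its excretion factor and measured metabolites.

    ``f_ue`` is the molar fraction of an ingested dose recovered in urine as
    the listed metabolites (jointly), so the daily-intake back-calculation
    sums molar excretion over all of them before dividing by ``f_ue``.
    """

    name: str
    mw_diester: float  # g/mol
    f_ue: float  # molar fraction in (0, 1]
    metabolites: tuple[MetaboliteSpec, ...]

    def __post_init__(self) -> None:
        if not 0 < self.f_ue <= 1:
            raise ValueError(f"f_ue must be in (0, 1] for {self.name}")
        if self.mw_diester <= 0:
            raise ValueError(f"mw_diester must be > 0 for {self.name}")
        if not self.metabolites:
            raise ValueError(f"parent {self.name} needs at least one metabolite")


@dataclass(frozen=True)
class TKParams:
    """One-compartment toxicokinetic parameters.

    t_half : elimination half-life in days.
    v_d : volume of distribution, L per kg body weight.
    ce : creatinine excretion rate, g creatinine per kg body weight per day.
    """

    t_half: float = 0.4
    v_d: float = 0.2
    ce: float = 0.023

    def __post_init__(self) -> None:
        if min(self.t_half, self.v_d, self.ce) <= 0:
            raise ValueError("all TK parameters must be strictly positive")


@dataclass(frozen=True)
class ConstantsConfig:
    """Full constant set: parent specs keyed by name plus TK parameters."""

    parents: Mapping[str, ParentSpec]
    tk: TKParams = field(default_factory=TKParams)
    version: int = 1

    def metabolite_index(self) -> dict[str, MetaboliteSpec]:
        """Map metabolite name -> spec; each metabolite has one parent."""
        idx: dict[str, MetaboliteSpec] = {}
        for p in self.parents.values():
            for m in p.metabolites:
                if m.name in idx:
                    raise ValueError(f"metabolite {m.name} listed under two parents")
                idx[m.name] = m
        return idx


@dataclass(frozen=True)
class BeEntry:
    """A guideline value (µg/L urine) and the metabolite columns it sums."""

    chemical: str
    be_ug_per_l: float
    basis: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.be_ug_per_l <= 0:
            raise ValueError(f"BE value must be > 0 for {self.chemical}")


@dataclass(frozen=True)
class BeTable:
    entries: Mapping[str, BeEntry]
    version: int = 1

    def __getitem__(self, chemical: str) -> BeEntry:
        return self.entries[chemical]

    def __iter__(self):
        return iter(self.entries.values())


def _parse_constants(doc: dict) -> ConstantsConfig:
    tk_doc = doc.get("toxicokinetics", {})
    tk = TKParams(
        t_half=float(tk_doc.get("t_half_days", 0.4)),
        v_d=float(tk_doc.get("v_d_l_per_kg", 0.2)),
        ce=float(tk_doc.get("ce_g_per_kg_day", 0.023)),
    )
    parents = {}
    for name, p in doc["parents"].items():
        mets = tuple(
            MetaboliteSpec(name=m, parent=name, mw_metabolite=float(mw))
            for m, mw in p["metabolites"].items()
        )
        parents[name] = ParentSpec(
            name=name,
            mw_diester=float(p["mw_diester"]),
            f_ue=float(p["f_ue"]),
            metabolites=mets,
        )
    return ConstantsConfig(parents=parents, tk=tk, version=int(doc.get("version", 1)))


def load_constants(path: str | Path) -> ConstantsConfig:
    """Load a constants config from a YAML file."""
    with open(path) as fh:
        return _parse_constants(yaml.safe_load(fh))


def default_constants() -> ConstantsConfig:
    """The packaged default constant set."""
    text = resources.files("smach.data").joinpath("constants.yaml").read_text()
    return _parse_constants(yaml.safe_load(text))


def _parse_be(doc: dict) -> BeTable:
    entries = {
        chem: BeEntry(
            chemical=chem,
            be_ug_per_l=float(e["be_ug_per_l"]),
            basis=tuple(e["basis"]),
        )
        for chem, e in doc["guidelines"].items()
    }
    return BeTable(entries=entries, version=int(doc.get("version", 1)))


def load_be_table(path: str | Path) -> BeTable:
    """Load a BE/HBM guideline table from a YAML file."""
    with open(path) as fh:
        return _parse_be(yaml.safe_load(fh))


def default_be_table() -> BeTable:
    """The packaged default BE/HBM guideline table."""
    text = resources.files("smach.data").joinpath("be_values.yaml").read_text()
    return _parse_be(yaml.safe_load(text))
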