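"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a plain stoichiometric network: metabolites,
reactions with signed coefficients and flux bounds, and a single objective
reaction (by convention the biomass pseudo-reaction).  Flux units are
mmol·gDW⁻¹·h⁻¹ throughout, except the biomass reaction whose flux is the
specific growth rate in h⁻¹.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "normalize_species_id",
    "models_equal",
]

DEFAULT_BOUND = 1000.0

_BRACKET_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")


def normalize_species_id(species_id: str) -> str:
    """Normalize a species identifier to BiGG suffix style.

    Bracketed compartment tags (``h[c]``) are converted to suffix style
    (``h_c``); suffix-style identifiers pass through unchanged.
    """
    m = _BRACKET_RE.match(species_id)
    if m:
        return f"{m.group('base')}_{m.group('comp')}"
    return species_id


def split_compartment(species_id: str) -> tuple[str, str]:
    """Split ``base_c`` into ``("base", "c")``; empty compartment if no suffix."""
    sid = normalize_species_id(species_id)
    if "_" in sid:
        base, comp = sid.rsplit("_", 1)
        if comp and len(comp) <= 2 and comp.isalnum():
            return base, comp
    return sid, ""


@dataclass
class Metabolite:
    """A chemical species in a fixed compartment."""

    id: str
    compartment: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        self.id = normalize_species_id(self.id)
        if not self.compartment:
            self.compartment = split_compartment(self.id)[1]


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    Negative coefficients are consumed, positive produced.  Coefficients may
    be NaN to mark a stoichiometry that still depends on an unresolved model
    parameter; such a model cannot be turned into an LP until resolved.
    """

    id: str
    stoich: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoich = {
            normalize_species_id(k): float(v)
            for k, v in self.stoich.items()
            if v != 0.0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: a single metabolite crossing the system boundary."""
        return len(self.stoich) == 1

    def has_unresolved_coefficients(self) -> bool:
        return any(math.isnan(v) for v in self.stoich.values())

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoich=dict(self.stoich),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds and a biomass objective."""

    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective_id: Optional[str] = None
    annotations: Dict[str, str] = field(default_factory=dict)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoich:
            if met_id not in self.metabolites:
                self.metabolites[met_id] = Metabolite(id=met_id)
        self.reactions[rxn.id] = rxn

    def check_consistency(self) -> None:
        """Raise if referenced metabolites or the objective are missing."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoich:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValueError(f"objective reaction {self.objective_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: Metabolite(v.id, v.compartment, v.name)
                         for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
        )

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def find_exchange(self, bases: Iterable[str],
                      compartments: Iterable[str] = ("e", "p", "c")) -> Optional[str]:
        """Locate the exchange reaction for a metabolite base name.

        Searches single-metabolite reactions whose species base name matches
        one of *bases*, preferring extracellular over periplasmic/cytosolic.
        """
        bases = {b.lower() for b in bases}
        by_comp: Dict[str, str] = {}
        for rxn in self.reactions.values():
            if not rxn.is_exchange:
                continue
            (met_id,) = rxn.stoich
            base, comp = split_compartment(met_id)
            if base.lower() in bases and comp not in by_comp:
                by_comp[comp] = rxn.id
        for comp in compartments:
            if comp in by_comp:
                return by_comp[comp]
        return None


def _coeff_equal(a: float, b: float, tol: float) -> bool:
    if math.isnan(a) and math.isnan(b):
        return True
    return abs(a - b) <= tol


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Structural equality on ids, bounds and coefficients (NaN == NaN)."""
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    if a.objective_id != b.objective_id:
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if set(ra.stoich) != set(rb.stoich):
            return False
        if not all(_coeff_equal(ra.stoich[m], rb.stoich[m], tol) for m in ra.stoich):
            return False
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
    return True
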