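"""Model input/output: SBML Level 3 FBC v2, BiGG-style JSON, TSV flux tables.

Reading goes through libsbml for SBML and the standard json module for the
BiGG dialect; both produce the same internal :class:`~poflux.model.MetabolicModel`.
Identifiers are normalized to BiGG suffix style (``h_c``); SBML ``M_``/``R_``
prefixes are stripped.  Writing SBML is out of scope — the JSON dump exists
so models (including the bundled core network) round-trip losslessly.
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import libsbml

from .errors import ConfigurationError, ModelIOError
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .po import ALL_ROLES, MANDATORY_ROLES, ETCRoleMap

__all__ = [
    "read_model",
    "write_model_json",
    "validate_model",
    "ValidationReport",
    "write_flux_table",
    "FLUX_TABLE_COLUMNS",
]


def read_model(path: str, fmt: str = "auto") -> MetabolicModel:
    """Read a genome-scale model from SBML (L3+FBC v2) or BiGG-style JSON.

    ``fmt`` is one of ``sbml_fbc``, ``bigg_json`` or ``auto`` (dispatch on
    extension; ``.gz`` compression is transparent).  The returned model
    carries all reactions, bounds and the file-declared objective.
    """
    if not os.path.exists(path):
        raise ModelIOError(f"model file not found: {path}")
    if fmt == "auto":
        stem = path[:-3] if path.endswith(".gz") else path
        ext = os.path.splitext(stem)[1].lower()
        if ext == ".json":
            fmt = "bigg_json"
        elif ext in (".xml", ".sbml"):
            fmt = "sbml_fbc"
        else:
            raise ConfigurationError(
                f"cannot infer model format from extension of {path!r}"
            )
    if fmt == "sbml_fbc":
        return _read_sbml(path)
    if fmt == "bigg_json":
        return _read_bigg_json(path)
    raise ConfigurationError(f"unknown model format {fmt!r}")


def _read_text(path: str) -> str:
    try:
        if path.endswith(".gz"):
            with gzip.open(path, "rt", encoding="utf-8") as fh:
                return fh.read()
        with open(path, "rt", encoding="utf-8") as fh:
            return fh.read()
    except OSError as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromString(_read_text(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msg = doc.getError(0).getMessage()
        raise ModelIOError(f"SBML parse error in {path}: {msg}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"no model element in {path}")
    if doc.getLevel() != 3:
        raise ConfigurationError(
            f"{path}: only SBML Level 3 with FBC v2 is supported "
            f"(got Level {doc.getLevel()})"
        )
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise ConfigurationError(
            f"{path}: SBML document lacks the FBC package (v2 required)"
        )

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(Metabolite(
            id=_strip_prefix(sp.getId(), "M_"),
            compartment=sp.getCompartment() or "",
            name=sp.getName() or "",
        ))

    params = {}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        params[p.getId()] = p.getValue()

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            sid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            sid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
        model.add_reaction(Reaction(
            id=_strip_prefix(rx.getId(), "R_"),
            stoich=stoich,
            lower_bound=lb, upper_bound=ub,
            name=rx.getName() or "",
        ))

    objective_id = None
    active = mplug.getActiveObjective()
    if active is not None:
        for j in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(j)
            if fo.getCoefficient() != 0.0:
                objective_id = _strip_prefix(fo.getReaction(), "R_")
                break
    if objective_id is None or objective_id not in model.reactions:
        raise ConfigurationError(f"{path}: model declares no usable objective")
    model.objective_id = objective_id
    model.check_consistency()
    return model


def _read_bigg_json(path: str) -> MetabolicModel:
    try:
        data = json.loads(_read_text(path))
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"invalid JSON in {path}: {exc}") from exc

    model = MetabolicModel(id=data.get("id", "model"))
    for met in data.get("metabolites", []):
        model.add_metabolite(Metabolite(
            id=met["id"],
            compartment=met.get("compartment", ""),
            name=met.get("name", ""),
        ))
    objective_id = None
    for rxn in data.get("reactions", []):
        model.add_reaction(Reaction(
            id=rxn["id"],
            stoich=dict(rxn.get("metabolites", {})),
            lower_bound=float(rxn.get("lower_bound", -DEFAULT_BOUND)),
            upper_bound=float(rxn.get("upper_bound", DEFAULT_BOUND)),
            name=rxn.get("name", ""),
        ))
        if rxn.get("objective_coefficient", 0.0):
            objective_id = rxn["id"]
    if objective_id is None:
        raise ConfigurationError(f"{path}: no reaction has a nonzero "
                                 "objective_coefficient")
    model.objective_id = objective_id
    model.annotations.update({str(k): str(v)
                              for k, v in data.get("annotations", {}).items()})
    model.check_consistency()
    return model


def write_model_json(model: MetabolicModel, path: str) -> None:
    """Dump a model to the BiGG-style JSON dialect (round-trips losslessly).

    Unresolved (NaN) coefficients are emitted as JSON ``NaN`` tokens, which
    the reader accepts back.
    """
    data = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoich),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions.values()
        ],
        "annotations": dict(model.annotations),
    }
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")
    except OSError as exc:
        raise ModelIOError(f"cannot write {path}: {exc}") from exc


_EXCHANGE_BASES = {
    "glucose": ("glc", "glc__D"),
    "oxygen": ("o2",),
    "acetate": ("ac",),
    "co2": ("co2",),
}


@dataclass
class ValidationReport:
    """Outcome of checking a model against an ETC role map (report-only)."""

    role_status: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    missing_mandatory: list = field(default_factory=list)
    exchange_status: Dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        """True iff every mandatory role resolves and key exchanges exist."""
        return not self.missing_mandatory and all(
            v is not None for v in self.exchange_status.values()
        )

    def summary(self) -> str:
        lines = []
        for role, status in self.role_status.items():
            if not status:
                lines.append(f"role {role}: no reaction mapped")
            else:
                for rid, present in status.items():
                    tag = "ok" if present else "MISSING"
                    lines.append(f"role {role}: {rid} [{tag}]")
        for name, rid in self.exchange_status.items():
            lines.append(f"exchange {name}: {rid or 'MISSING'}")
        if self.missing_mandatory:
            lines.append("missing mandatory roles: "
                         + ", ".join(self.missing_mandatory))
        return "\n".join(lines)


def validate_model(model: MetabolicModel, roles: ETCRoleMap) -> ValidationReport:
    """Report, per canonical ETC role, whether a reaction id resolves.

    Also flags missing glucose/oxygen/acetate/CO2 exchange reactions.  The
    model is never mutated; scan drivers refuse models whose report lists
    missing mandatory roles.
    """
    report = ValidationReport()
    for role in ALL_ROLES:
        rids = roles.get(role)
        report.role_status[role] = {rid: rid in model.reactions for rid in rids}
    report.missing_mandatory = roles.missing_mandatory(model)
    for name, bases in _EXCHANGE_BASES.items():
        report.exchange_status[name] = model.find_exchange(bases)
    return report


FLUX_TABLE_COLUMNS = (
    "scenario", "po", "growth_rate", "glucose_uptake", "oxygen_uptake",
    "acetate_secretion", "co2_secretion", "bo_flux", "bd_flux", "status",
)


def write_flux_table(results, path: str) -> None:
    """Write one or several scan results as a TSV flux table.

    One row per (scenario, P/O grid point); infeasible points keep their row
    with empty flux cells.  Fluxes are mmol·gDW⁻¹·h⁻¹, growth h⁻¹; decimal
    point is ".", delimiter a tab.
    """
    rows = list(_iter_flux_rows(results))
    if not rows:
        raise ValueError("cannot write an empty flux table")
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(FLUX_TABLE_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
    except OSError as exc:
        raise ModelIOError(f"cannot write flux table {path}: {exc}") from exc


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return format(float(value), ".10g")


def _iter_flux_rows(results):
    from .scan import ScanResult  # local import to avoid a cycle

    if isinstance(results, ScanResult):
        results = [results]
    for res in results:
        for rec in res.records:
            yield (
                res.scenario.label,
                _fmt(rec.po),
                _fmt(rec.growth_rate),
                _fmt(rec.q_glc),
                _fmt(rec.q_o2),
                _fmt(rec.q_ac),
                _fmt(rec.q_co2),
                _fmt(rec.bo_flux),
                _fmt(rec.bd_flux),
                rec.status,
            )
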