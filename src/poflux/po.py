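"""P/O-ratio parameterization of the E. coli electron transport chain.

The P/O ratio (ATP per NADH-equivalent electron pair, i.e. per ½ O₂
reduced) is imposed on a model by rewriting the proton stoichiometry of
the respiratory dehydrogenases and terminal oxidases.  With P := P/O:

=========================================  =============================================
role                                       stoichiometry
=========================================  =============================================
translocating NADH dehydrogenase (NDH-1)   (2P+1) h_c + nadh + Q  → nad + QH₂ + (2P) h_p
formate dehydrogenase                      (2P+1) h_c + q8 + for_p → q8h2 + co2_p + (2P) h_p
cytochrome bd oxidase (ubiquinol/menaq.)   (P) h_c + ½ o2 + QH₂   → h2o + Q + (P) h_p
cytochrome bo oxidase                      (2P) h_c + ½ o2 + q8h2 → h2o + q8 + (2P) h_p
=========================================  =============================================

Q/QH₂ is each reaction's native quinone pair (ubiquinone-8, menaquinone-8
or demethylmenaquinone-8), taken from the template reaction rather than
hard-coded.  The non-translocating NADH dehydrogenase (NDH-2) keeps a zero
periplasmic-proton coefficient; a switch is provided to give it the NDH-1
pattern instead, since its membership in the rewritten set is a matter of
interpretation.  ATP synthase is never rewritten.

Every dehydrogenase nets one cytosolic proton ((2P+1) − 2P) and every
oxidase nets zero (2P − 2P or P − P) at any P; :func:`proton_audit`
re-checks this on a parameterized model.

Theoretically the E. coli P/O ratio ranges from 0.67 (NDH-2 + bd) to 2.67
(NDH-1 + bo); scans restrict P to [0.67, 2.67].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

from .errors import ConfigurationError
from .model import MetabolicModel, Reaction

__all__ = [
    "NADH_DH_TRANSLOCATING",
    "NADH_DH_NONTRANSLOCATING",
    "FORMATE_DH",
    "CYT_BD_UBIQUINOL",
    "CYT_BD_MENAQUINOL",
    "CYT_BO",
    "ALL_ROLES",
    "MANDATORY_ROLES",
    "DEHYDROGENASE_ROLES",
    "OXIDASE_ROLES",
    "ETCRoleMap",
    "ijo1366_role_map",
    "PO_MIN",
    "PO_MAX",
    "apply_po_ratio",
    "proton_audit",
]

NADH_DH_TRANSLOCATING = "nadh_dehydrogenase_translocating"
NADH_DH_NONTRANSLOCATING = "nadh_dehydrogenase_nontranslocating"
FORMATE_DH = "formate_dehydrogenase"
CYT_BD_UBIQUINOL = "cytochrome_bd_ubiquinol"
CYT_BD_MENAQUINOL = "cytochrome_bd_menaquinol"
CYT_BO = "cytochrome_bo"

ALL_ROLES = (
    NADH_DH_TRANSLOCATING,
    NADH_DH_NONTRANSLOCATING,
    FORMATE_DH,
    CYT_BD_UBIQUINOL,
    CYT_BD_MENAQUINOL,
    CYT_BO,
)

#: Roles a scan cannot run without.
MANDATORY_ROLES = (NADH_DH_TRANSLOCATING, CYT_BO, CYT_BD_UBIQUINOL)

DEHYDROGENASE_ROLES = (NADH_DH_TRANSLOCATING, NADH_DH_NONTRANSLOCATING, FORMATE_DH)
OXIDASE_ROLES = (CYT_BD_UBIQUINOL, CYT_BD_MENAQUINOL, CYT_BO)

#: Theoretical E. coli range: NDH-2 + bd up to NDH-1 + bo.
PO_MIN = 0.67
PO_MAX = 2.67

# Recognized quinone/quinol pairs, by species base name.
_QUINONE_PAIRS = (("q8", "q8h2"), ("mqn8", "mql8"), ("2dmmq8", "2dmmql8"))


@dataclass(frozen=True)
class ETCRoleMap:
    """Mapping from canonical electron-transport-chain roles to reaction ids.

    The translocating NADH dehydrogenase role may carry several reaction ids
    (NDH-1 paralogs with different quinone specificity); the other roles at
    most one.  A reaction id may not serve two roles.
    """

    roles: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: Dict[str, Tuple[str, ...]] = {}
        for role, rids in dict(self.roles).items():
            if role not in ALL_ROLES:
                raise ConfigurationError(f"unknown ETC role {role!r}")
            if isinstance(rids, str):
                rids = (rids,)
            norm[role] = tuple(rids)
        seen: Dict[str, str] = {}
        for role, rids in norm.items():
            for rid in rids:
                if rid in seen:
                    raise ConfigurationError(
                        f"reaction {rid!r} mapped to both {seen[rid]!r} and {role!r}"
                    )
                seen[rid] = role
        object.__setattr__(self, "roles", norm)

    def get(self, role: str) -> Tuple[str, ...]:
        return self.roles.get(role, ())

    def items(self) -> Iterator[Tuple[str, Tuple[str, ...]]]:
        return iter(self.roles.items())

    def missing_mandatory(self, model: MetabolicModel) -> list[str]:
        """Mandatory roles with no reaction id resolving in *model*."""
        missing = []
        for role in MANDATORY_ROLES:
            rids = self.get(role)
            if not rids or not any(r in model.reactions for r in rids):
                missing.append(role)
        return missing


def ijo1366_role_map() -> ETCRoleMap:
    """Default role map for the iJO1366 genome-scale E. coli model."""
    return ETCRoleMap({
        NADH_DH_TRANSLOCATING: ("NADH16pp", "NADH17pp", "NADH18pp"),
        NADH_DH_NONTRANSLOCATING: ("NADH10",),
        FORMATE_DH: ("FDH4pp",),
        CYT_BD_UBIQUINOL: ("CYTBDpp",),
        CYT_BD_MENAQUINOL: ("CYTBD2pp",),
        CYT_BO: ("CYTBO3_4pp",),
    })


def _species(model: MetabolicModel, base: str, comp: str, rid: str) -> str:
    sid = f"{base}_{comp}"
    if sid not in model.metabolites:
        raise ConfigurationError(
            f"cannot rewrite {rid}: species {sid!r} absent from model"
        )
    return sid


def _native_quinone_pair(rxn: Reaction, oxidized_first: bool) -> Tuple[str, str]:
    """Return (consumed, produced) quinone species of a template reaction."""
    for q, qh2 in _QUINONE_PAIRS:
        found_q = found_qh2 = None
        for sid in rxn.stoich:
            base = sid.rsplit("_", 1)[0] if "_" in sid else sid
            if base == q:
                found_q = sid
            elif base == qh2:
                found_qh2 = sid
        if found_q and found_qh2:
            if oxidized_first:
                return found_q, found_qh2
            return found_qh2, found_q
    raise ConfigurationError(
        f"cannot rewrite {rxn.id}: no recognized quinone/quinol pair in "
        f"{sorted(rxn.stoich)}"
    )


def apply_po_ratio(
    template: MetabolicModel,
    po: float,
    roles: ETCRoleMap,
    nadh2_translocating: bool = False,
) -> MetabolicModel:
    """Return a copy of *template* with the ETC rewritten for P/O = *po*.

    Only reactions named in *roles* are touched; bounds and the objective
    are preserved.  Re-application with a different P/O on the same template
    always yields the stoichiometry of the new value only (the patterns are
    absolute, so compounding is impossible).

    Parameters
    ----------
    po:
        The target P/O ratio; must be positive.
    nadh2_translocating:
        If true, the non-translocating NADH dehydrogenase also receives the
        NDH-1 pumping pattern (alternate reading of which dehydrogenases
        are rewritten).  Default leaves it untouched, consistent with NDH-2
        biochemistry.
    """
    if not (po > 0.0) or math.isnan(po):
        raise ConfigurationError(f"P/O ratio must be positive, got {po}")
    missing = roles.missing_mandatory(template)
    if missing:
        raise ConfigurationError(
            "role map does not resolve mandatory roles in model: "
            + ", ".join(missing)
        )
    model = template.copy()
    p = float(po)

    def rewrite(rid: str, stoich: Dict[str, float]) -> None:
        old = model.reactions[rid]
        model.reactions[rid] = Reaction(
            id=rid, stoich=stoich,
            lower_bound=old.lower_bound, upper_bound=old.upper_bound,
            name=old.name,
        )

    for rid in roles.get(NADH_DH_TRANSLOCATING):
        if rid not in model.reactions:
            continue
        rxn = model.reactions[rid]
        q, qh2 = _native_quinone_pair(rxn, oxidized_first=True)
        rewrite(rid, {
            _species(model, "h", "c", rid): -(2 * p + 1),
            _species(model, "nadh", "c", rid): -1.0,
            q: -1.0,
            _species(model, "nad", "c", rid): 1.0,
            qh2: 1.0,
            _species(model, "h", "p", rid): 2 * p,
        })

    for rid in roles.get(FORMATE_DH):
        if rid not in model.reactions:
            continue
        rxn = model.reactions[rid]
        q, qh2 = _native_quinone_pair(rxn, oxidized_first=True)
        rewrite(rid, {
            _species(model, "h", "c", rid): -(2 * p + 1),
            q: -1.0,
            _species(model, "for", "p", rid): -1.0,
            qh2: 1.0,
            _species(model, "co2", "p", rid): 1.0,
            _species(model, "h", "p", rid): 2 * p,
        })

    for role, pump in ((CYT_BD_UBIQUINOL, p), (CYT_BD_MENAQUINOL, p), (CYT_BO, 2 * p)):
        for rid in roles.get(role):
            if rid not in model.reactions:
                continue
            rxn = model.reactions[rid]
            qh2, q = _native_quinone_pair(rxn, oxidized_first=False)
            rewrite(rid, {
                _species(model, "h", "c", rid): -pump,
                _species(model, "o2", "c", rid): -0.5,
                qh2: -1.0,
                _species(model, "h2o", "c", rid): 1.0,
                q: 1.0,
                _species(model, "h", "p", rid): pump,
            })

    if nadh2_translocating:
        for rid in roles.get(NADH_DH_NONTRANSLOCATING):
            if rid not in model.reactions:
                continue
            rxn = model.reactions[rid]
            q, qh2 = _native_quinone_pair(rxn, oxidized_first=True)
            rewrite(rid, {
                _species(model, "h", "c", rid): -(2 * p + 1),
                _species(model, "nadh", "c", rid): -1.0,
                q: -1.0,
                _species(model, "nad", "c", rid): 1.0,
                qh2: 1.0,
                _species(model, "h", "p", rid): 2 * p,
            })

    model.annotations["po_ratio"] = repr(p)
    return model


@dataclass
class ProtonAuditEntry:
    reaction_id: str
    role: str
    net_cytosolic_protons: float  #: h_c consumed minus h_p produced
    expected: float
    ok: bool


def proton_audit(model: MetabolicModel, roles: ETCRoleMap,
                 tol: float = 1e-9) -> list[ProtonAuditEntry]:
    """Check proton bookkeeping of every parameterized ETC reaction.

    For any P/O, a dehydrogenase must consume exactly one cytosolic proton
    net of pumping ((2P+1) − 2P) and an oxidase exactly zero; a deviation
    indicates a transcription or rewrite bug.
    """
    entries = []
    for role, rids in roles.items():
        expected = 1.0 if role in DEHYDROGENASE_ROLES else 0.0
        for rid in rids:
            rxn = model.reactions.get(rid)
            if rxn is None:
                continue
            hc = hp = 0.0
            for sid, coeff in rxn.stoich.items():
                base, comp = (sid.rsplit("_", 1) + [""])[:2] if "_" in sid else (sid, "")
                if base == "h" and comp == "c" and coeff < 0:
                    hc += -coeff
                elif base == "h" and comp == "p" and coeff > 0:
                    hp += coeff
            net = hc - hp
            entries.append(ProtonAuditEntry(
                reaction_id=rid, role=role,
                net_cytosolic_protons=net, expected=expected,
                ok=bool(abs(net - expected) <= tol),
            ))
    return entries
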