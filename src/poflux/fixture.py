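"""A small E. coli-like core network exhibiting acetate overflow.

The network stands in for a genome-scale model so that every stage of the
pipeline — ETC parameterization, FBA/pFBA, scenario scans — runs in
milliseconds with no external files.  It lumps central carbon metabolism
into a handful of reactions while preserving the trade-off that produces
overflow metabolism:

* respiration (PDH → TCA → NADH → electron transport chain) is
  carbon-efficient but oxygen-expensive;
* the overflow branch (PFL → phosphotransacetylase/acetate kinase) yields
  ATP with no oxygen demand but wastes carbon as acetate and formate.

Redox bookkeeping is deliberately assigned to the respiratory branch: the
lumped glycolysis is redox-neutral and NADH appears at pyruvate
dehydrogenase and the TCA lump.  This mirrors how, in genome-scale E. coli
models, overflow carbon leaves through pyruvate-formate lyase without a
net NADH burden, and it is what makes acetate secretion fall — never
rise — as oxygen supply or the P/O ratio increases.

The four electron-transport reactions (NADH16, NADH10, CYTBO, CYTBD)
follow the same proton-pumping patterns used for the genome-scale rewrite;
their P/O-dependent proton coefficients are built as NaN placeholders and
the model is not solvable until :func:`poflux.po.apply_po_ratio` resolves
them.

Closure exchanges: phosphate, cytosolic protons and water are freely
exchangeable (they are medium components/byproducts); the periplasmic
proton exchange is secretion-only, since a free periplasmic proton supply
plus reversible ATP synthase would amount to an unbounded ATP source.
"""

from __future__ import annotations

from typing import Optional

from .model import DEFAULT_BOUND, MetabolicModel, Reaction
from .po import (
    CYT_BD_UBIQUINOL,
    CYT_BO,
    ETCRoleMap,
    NADH_DH_NONTRANSLOCATING,
    NADH_DH_TRANSLOCATING,
)

__all__ = ["build_core_fixture", "fixture_role_map",
           "ATPM_LOWER_BOUND", "BIOMASS_ATP_COEFF", "CARBON_PER_BIOMASS"]

#: Non-growth-associated maintenance, mmol ATP gDW⁻¹ h⁻¹ (the published
#: iJO1366 default, so core and genome-scale runs share the convention).
ATPM_LOWER_BOUND = 3.15

#: ATP demand of the biomass equation, mmol per gDW.  Sized so that at
#: qS = −11 the optimum secretes acetate whenever oxygen is limiting, and
#: the oxygen constraint goes slack (acetate → 0) at high P/O under the
#: highest oxygen-uptake scenario.
BIOMASS_ATP_COEFF = 65.0

#: Glucose-carbon equivalents drained per unit biomass flux
#: (2 g6p + 3 pyr + 12 accoa → 12 + 9 + 24 = 45 carbons).
CARBON_PER_BIOMASS = 45.0

_NAN = float("nan")


def build_core_fixture(atp_coeff: float = BIOMASS_ATP_COEFF,
                       atpm_lower_bound: float = ATPM_LOWER_BOUND) -> MetabolicModel:
    """Build the core overflow network (17 internal reactions, 10 exchanges).

    The returned model carries NaN placeholders for the P/O-dependent
    proton coefficients of NADH16, CYTBO and CYTBD; resolve them with
    :func:`poflux.po.apply_po_ratio` before building an LP.
    """
    b = float(atp_coeff)
    model = MetabolicModel(id="ecoli_core_overflow")
    model.annotations["description"] = (
        "lumped E. coli core network with acetate overflow and a "
        "P/O-parameterized electron transport chain"
    )

    def rxn(rid, stoich, lb=0.0, ub=DEFAULT_BOUND, name=""):
        model.add_reaction(Reaction(id=rid, stoich=stoich,
                                    lower_bound=lb, upper_bound=ub, name=name))

    # --- carbon backbone -------------------------------------------------
    rxn("GLCpts", {"glc_e": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
        name="glucose PTS uptake")
    rxn("GLYC", {"g6p_c": -1, "adp_c": -2, "pi_c": -2,
                 "pyr_c": 2, "atp_c": 2, "h2o_c": 2},
        name="lumped glycolysis (redox-neutral)")
    rxn("PDH", {"pyr_c": -1, "nad_c": -1, "coa_c": -1,
                "accoa_c": 1, "nadh_c": 1, "co2_c": 1},
        name="pyruvate dehydrogenase")
    rxn("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
        name="pyruvate formate lyase")
    rxn("TCA", {"accoa_c": -1, "nad_c": -3, "fad_c": -1, "adp_c": -1,
                "pi_c": -1, "h2o_c": -2,
                "coa_c": 1, "co2_c": 2, "nadh_c": 3, "fadh2_c": 1,
                "atp_c": 1, "h_c": 2},
        name="lumped TCA cycle")
    rxn("PTACK", {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
                  "ac_c": 1, "atp_c": 1, "coa_c": 1},
        name="phosphotransacetylase + acetate kinase")
    rxn("ACt", {"ac_c": -1, "ac_e": 1}, name="acetate export")

    # --- electron transport chain (P/O-dependent entries unresolved) -----
    rxn("SDH", {"fadh2_c": -1, "q8_c": -1, "fad_c": 1, "q8h2_c": 1},
        name="succinate dehydrogenase lump")
    rxn("NADH16", {"h_c": -_NAN, "nadh_c": -1, "q8_c": -1,
                   "nad_c": 1, "q8h2_c": 1, "h_p": _NAN},
        name="NADH dehydrogenase I (translocating)")
    rxn("NADH10", {"nadh_c": -1, "q8_c": -1, "h_c": -1,
                   "nad_c": 1, "q8h2_c": 1},
        name="NADH dehydrogenase II (non-translocating)")
    rxn("CYTBO", {"h_c": -_NAN, "o2_c": -0.5, "q8h2_c": -1,
                  "h2o_c": 1, "q8_c": 1, "h_p": _NAN},
        name="cytochrome bo oxidase")
    rxn("CYTBD", {"h_c": -_NAN, "o2_c": -0.5, "q8h2_c": -1,
                  "h2o_c": 1, "q8_c": 1, "h_p": _NAN},
        name="cytochrome bd oxidase")
    rxn("ATPS", {"adp_c": -1, "pi_c": -1, "h_p": -4,
                 "atp_c": 1, "h2o_c": 1, "h_c": 3},
        lb=-DEFAULT_BOUND, name="ATP synthase (4 h_p per ATP)")
    rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        lb=float(atpm_lower_bound), name="non-growth maintenance")

    # --- transport and biomass -------------------------------------------
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, name="oxygen diffusion")
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, name="CO2 diffusion")
    rxn("BIOMASS", {"g6p_c": -2, "pyr_c": -3, "accoa_c": -12,
                    "atp_c": -b, "h2o_c": -b,
                    "adp_c": b, "pi_c": b, "h_c": b,
                    "coa_c": 12, "biomass_e": 1},
        name="biomass assembly")

    # --- exchanges ---------------------------------------------------------
    rxn("EX_glc", {"glc_e": -1}, lb=-11.0, ub=0.0, name="glucose exchange")
    rxn("EX_o2", {"o2_e": -1}, lb=-8.0, ub=0.0, name="oxygen exchange")
    rxn("EX_ac", {"ac_e": -1}, name="acetate secretion")
    rxn("EX_for", {"for_c": -1}, name="formate secretion")
    rxn("EX_co2", {"co2_e": -1}, name="CO2 secretion")
    rxn("EX_h", {"h_p": -1}, name="periplasmic proton venting (secretion-only)")
    rxn("EX_hc", {"h_c": -1}, lb=-DEFAULT_BOUND, name="cytosolic proton buffer")
    rxn("EX_pi", {"pi_c": -1}, lb=-DEFAULT_BOUND, name="phosphate exchange")
    rxn("EX_h2o", {"h2o_c": -1}, lb=-DEFAULT_BOUND, name="water exchange")
    rxn("EX_biomass", {"biomass_e": -1}, name="biomass drain")

    model.objective_id = "BIOMASS"
    model.check_consistency()
    return model


def fixture_role_map() -> ETCRoleMap:
    """ETC role map for the core fixture (no menaquinol or formate roles)."""
    return ETCRoleMap({
        NADH_DH_TRANSLOCATING: ("NADH16",),
        NADH_DH_NONTRANSLOCATING: ("NADH10",),
        CYT_BO: ("CYTBO",),
        CYT_BD_UBIQUINOL: ("CYTBD",),
    })
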