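"""Scenario × P/O-ratio scan of oxygen-constrained biomass maximization.

A scenario fixes the maximum glucose and oxygen uptake rates (negative
exchange lower bounds; the optimizer may use less) and an oxygen-uptake
multiplier representing Vitreoscilla haemoglobin (VHb) expression, which
is modelled solely as a 25 % higher oxygen-uptake capacity.  For each P/O
grid point the template model is re-parameterized from scratch, the
uptake bounds applied, FBA solved for the maximal growth rate, and pFBA
used to pick the canonical (minimal-total-flux) flux distribution among
alternate optima.  Cytochrome bo/bd fluxes also carry FVA ranges at the
optimum, so a degenerate oxidase choice is visible rather than
solver-arbitrary.

Diagnostics: the smallest P/O at which the bd-type oxidase overtakes the
bo-type (:func:`detect_switch_point`), the P/O after which a quantity
(e.g. the CO₂ evolution rate) starts to strictly decrease
(:func:`detect_turning_point`), and pointwise scenario comparisons
(:func:`compare_scenarios`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PofluxError
from .fba import FLUX_ZERO_TOL, build_lp, fva, solve_fba, solve_pfba
from .model import MetabolicModel
from .po import (
    CYT_BD_MENAQUINOL,
    CYT_BD_UBIQUINOL,
    CYT_BO,
    ETCRoleMap,
    apply_po_ratio,
)

__all__ = [
    "ScanScenario",
    "POGrid",
    "ScanRecord",
    "ScanResult",
    "default_scenarios",
    "run_po_scan",
    "detect_switch_point",
    "detect_turning_point",
    "compare_scenarios",
    "VHB_O2_MULTIPLIER",
]

#: VHb raises the attainable oxygen uptake rate by 25 %.
VHB_O2_MULTIPLIER = 1.25


@dataclass(frozen=True)
class ScanScenario:
    """Uptake constraints for one condition.

    ``q_glc`` and ``q_o2`` are maximum uptake rates as negative exchange
    fluxes (mmol·gDW⁻¹·h⁻¹); ``vhb_multiplier`` ≥ 1 scales the oxygen
    capacity.
    """

    label: str
    q_glc: float
    q_o2: float
    vhb_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.q_glc < 0:
            raise ConfigurationError(f"{self.label}: q_glc must be negative")
        if not self.q_o2 < 0:
            raise ConfigurationError(f"{self.label}: q_o2 must be negative")
        if self.vhb_multiplier < 1.0:
            raise ConfigurationError(
                f"{self.label}: vhb_multiplier must be ≥ 1"
            )

    @property
    def effective_q_o2(self) -> float:
        return self.q_o2 * self.vhb_multiplier


def default_scenarios() -> List[ScanScenario]:
    """The four study conditions: wild type and VHb at two oxygen capacities.

    Glucose uptake capacity is −11 mmol·gDW⁻¹·h⁻¹ throughout; oxygen is
    −8 (relatively low) or −15 (maximum capacity), with VHb granting 25 %
    more oxygen in each case (effective −10 and −18.75).
    """
    return [
        ScanScenario("WT-low", q_glc=-11.0, q_o2=-8.0),
        ScanScenario("VHb-low", q_glc=-11.0, q_o2=-8.0,
                     vhb_multiplier=VHB_O2_MULTIPLIER),
        ScanScenario("WT-max", q_glc=-11.0, q_o2=-15.0),
        ScanScenario("VHb-max", q_glc=-11.0, q_o2=-15.0,
                     vhb_multiplier=VHB_O2_MULTIPLIER),
    ]


@dataclass(frozen=True)
class POGrid:
    """An inclusive P/O grid [lo, hi] with fixed step."""

    lo: float = 0.67
    hi: float = 2.67
    step: float = 0.05

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigurationError("grid lo must not exceed hi")
        if not self.step > 0:
            raise ConfigurationError("grid step must be positive")

    def points(self) -> List[float]:
        """Grid points lo, lo+step, … up to hi (hi included when on-grid)."""
        pts = []
        k = 0
        while True:
            p = self.lo + k * self.step
            if p > self.hi + 1e-9:
                break
            pts.append(round(p, 10))
            k += 1
        return pts


@dataclass
class ScanRecord:
    """Diagnostics of one (scenario, P/O) grid point."""

    po: float
    status: str
    growth_rate: Optional[float] = None
    q_glc: Optional[float] = None
    q_o2: Optional[float] = None
    q_ac: Optional[float] = None
    q_co2: Optional[float] = None
    bo_flux: Optional[float] = None
    bd_flux: Optional[float] = None
    bo_range: Optional[Tuple[float, float]] = None
    bd_range: Optional[Tuple[float, float]] = None
    total_absolute_flux: Optional[float] = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


@dataclass
class ScanResult:
    """All grid points of one scenario, sorted ascending in P/O."""

    scenario: ScanScenario
    grid: POGrid
    records: List[ScanRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "scenario": self.scenario.label,
                "po": r.po,
                "status": r.status,
                "growth_rate": r.growth_rate,
                "q_glc": r.q_glc,
                "q_o2": r.q_o2,
                "q_ac": r.q_ac,
                "q_co2": r.q_co2,
                "bo_flux": r.bo_flux,
                "bd_flux": r.bd_flux,
                "bo_min": r.bo_range[0] if r.bo_range else None,
                "bo_max": r.bo_range[1] if r.bo_range else None,
                "bd_min": r.bd_range[0] if r.bd_range else None,
                "bd_max": r.bd_range[1] if r.bd_range else None,
            })
        return pd.DataFrame(rows)

    def series(self, column: str) -> List[Tuple[float, float]]:
        """(po, value) pairs over feasible points for a record attribute."""
        return [(r.po, getattr(r, column)) for r in self.records if r.feasible]


def _role_flux(fluxes: Dict[str, float], roles: ETCRoleMap,
               role_names: Sequence[str], model: MetabolicModel) -> float:
    total = 0.0
    for role in role_names:
        for rid in roles.get(role):
            if rid in fluxes:
                total += fluxes[rid]
    return total


def run_po_scan(
    template: MetabolicModel,
    roles: ETCRoleMap,
    scenario: ScanScenario,
    grid: POGrid,
    *,
    glucose_exchange: Optional[str] = None,
    oxygen_exchange: Optional[str] = None,
    with_fva: bool = True,
    nadh2_translocating: bool = False,
    po_values: Optional[Sequence[float]] = None,
) -> ScanResult:
    """Scan one scenario over the P/O grid.

    Each grid point rebuilds the model from the untouched template via
    :func:`~poflux.po.apply_po_ratio` (so re-parameterization can never
    compound), imposes the scenario's uptake bounds as exchange lower
    bounds with upper bound 0, and records FBA growth plus pFBA fluxes.
    Infeasible points are recorded, not dropped.
    """
    missing = roles.missing_mandatory(template)
    if missing:
        raise ConfigurationError(
            "template does not resolve mandatory ETC roles: " + ", ".join(missing)
        )
    glucose_exchange = glucose_exchange or template.find_exchange(("glc", "glc__D"))
    oxygen_exchange = oxygen_exchange or template.find_exchange(("o2",))
    if glucose_exchange is None or oxygen_exchange is None:
        raise ConfigurationError(
            "cannot locate glucose/oxygen exchange reactions; pass "
            "glucose_exchange/oxygen_exchange explicitly"
        )
    acetate_exchange = template.find_exchange(("ac",))
    co2_exchange = template.find_exchange(("co2",))

    oxidase_ids = [rid for role in (CYT_BO, CYT_BD_UBIQUINOL, CYT_BD_MENAQUINOL)
                   for rid in roles.get(role) if rid in template.reactions]

    result = ScanResult(scenario=scenario, grid=grid)
    for po in (sorted(po_values) if po_values is not None else grid.points()):
        model = apply_po_ratio(template, po, roles,
                               nadh2_translocating=nadh2_translocating)
        lp = build_lp(model)
        lp = lp.with_bounds(glucose_exchange, scenario.q_glc, 0.0)
        lp = lp.with_bounds(oxygen_exchange, scenario.effective_q_o2, 0.0)
        sol = solve_fba(lp)
        if not sol.optimal:
            result.records.append(ScanRecord(po=po, status=sol.status))
            continue
        mu = sol.objective_value
        psol = solve_pfba(lp, mu)
        fluxes = psol.fluxes if psol.optimal else sol.fluxes

        def clean(value):
            # solver noise below bound tolerance is reported as an exact zero
            if value is not None and abs(value) < 1e-9:
                return 0.0
            return value

        rec = ScanRecord(
            po=po,
            status="optimal",
            growth_rate=mu,
            q_glc=clean(fluxes.get(glucose_exchange)),
            q_o2=clean(fluxes.get(oxygen_exchange)),
            q_ac=clean(fluxes.get(acetate_exchange)) if acetate_exchange else None,
            q_co2=clean(fluxes.get(co2_exchange)) if co2_exchange else None,
            bo_flux=clean(_role_flux(fluxes, roles, (CYT_BO,), model)),
            bd_flux=clean(_role_flux(fluxes, roles,
                                     (CYT_BD_UBIQUINOL, CYT_BD_MENAQUINOL),
                                     model)),
            total_absolute_flux=psol.total_absolute_flux,
        )
        if with_fva and oxidase_ids:
            ranges = fva(lp, oxidase_ids, fraction=1.0, optimum=mu)
            bo_ids = [r for r in roles.get(CYT_BO) if r in ranges]
            bd_ids = [r for role in (CYT_BD_UBIQUINOL, CYT_BD_MENAQUINOL)
                      for r in roles.get(role) if r in ranges]
            if bo_ids:
                rec.bo_range = (sum(ranges[r][0] for r in bo_ids),
                                sum(ranges[r][1] for r in bo_ids))
            if bd_ids:
                rec.bd_range = (sum(ranges[r][0] for r in bd_ids),
                                sum(ranges[r][1] for r in bd_ids))
        result.records.append(rec)
    return result


@dataclass
class SwitchPoint:
    """Outcome of the oxidase-replacement search."""

    po: Optional[float]
    annotations: List[str] = field(default_factory=list)


_ROLE_COLUMNS = {
    CYT_BO: ("bo_flux", "bo_range"),
    CYT_BD_UBIQUINOL: ("bd_flux", "bd_range"),
    CYT_BD_MENAQUINOL: ("bd_flux", "bd_range"),
}


def detect_switch_point(
    result: ScanResult,
    role_a: str = CYT_BO,
    role_b: str = CYT_BD_UBIQUINOL,
    zero_tol: float = FLUX_ZERO_TOL,
) -> SwitchPoint:
    """Smallest grid P/O at which oxidase *role_b* overtakes *role_a*.

    Uses pFBA fluxes: returns the first grid point where flux(role_b)
    exceeds flux(role_a) while the preceding feasible point still had
    flux(role_a) ≥ flux(role_b); ``None`` if the ordering never flips.
    Points where FVA shows the trailing oxidase could nevertheless carry
    flux at the optimum are annotated as degenerate.
    """
    try:
        col_a, rng_a = _ROLE_COLUMNS[role_a]
        col_b, rng_b = _ROLE_COLUMNS[role_b]
    except KeyError as exc:
        raise ConfigurationError(
            f"switch detection tracks oxidase roles only, got {exc}"
        ) from None
    feasible = [r for r in result.records if r.feasible]
    if len(feasible) < 2:
        raise PofluxError("switch detection needs at least two feasible points")
    if len(feasible) < len(result.records):
        warnings.warn("infeasible grid points skipped in switch detection")
    annotations = []
    for rec in feasible:
        fa, fb = getattr(rec, col_a), getattr(rec, col_b)
        if fa is None or fb is None:
            continue
        minor_rng = getattr(rec, rng_b if fb <= fa else rng_a)
        if minor_rng and min(fa, fb) <= zero_tol < minor_rng[1]:
            annotations.append(
                f"P/O={rec.po:g}: oxidase choice degenerate "
                f"(unused oxidase can carry up to {minor_rng[1]:.3g} at optimum)"
            )
    switch = None
    for prev, cur in zip(feasible, feasible[1:]):
        pa, pb = getattr(prev, col_a), getattr(prev, col_b)
        ca, cb = getattr(cur, col_a), getattr(cur, col_b)
        if None in (pa, pb, ca, cb):
            continue
        if pa >= pb - zero_tol and cb > ca + zero_tol:
            switch = cur.po
            break
    return SwitchPoint(po=switch, annotations=annotations)


_TURNING_COLUMNS = {"q_co2": "q_co2", "q_ac": "q_ac", "mu": "growth_rate"}


def detect_turning_point(
    result: ScanResult,
    quantity: str = "q_co2",
    tol: float = FLUX_ZERO_TOL,
) -> Optional[float]:
    """Smallest grid P/O after which *quantity* strictly decreases.

    ``quantity`` is one of ``q_co2``, ``q_ac`` or ``mu``.  Returns the grid
    P/O of the peak — the point after which every subsequent feasible value
    strictly decreases (by more than *tol*) — or ``None`` for a monotone
    series.  The peak must be an interior rise-then-fall point.
    """
    try:
        column = _TURNING_COLUMNS[quantity]
    except KeyError:
        raise ConfigurationError(
            f"quantity must be one of {sorted(_TURNING_COLUMNS)}, got {quantity!r}"
        ) from None
    series = result.series(column)
    if len(series) < 3:
        raise PofluxError("turning-point detection needs ≥ 3 feasible points")
    if len(series) < len(result.records):
        warnings.warn("infeasible grid points skipped in turning detection")
    pos = [p for p, _ in series]
    vals = [v for _, v in series]
    for i in range(1, len(vals) - 1):
        if vals[i] < vals[i - 1] - tol:
            continue  # not a rise into i
        if all(vals[j] < vals[j - 1] - tol for j in range(i + 1, len(vals))):
            return pos[i]
    return None


@dataclass
class ScenarioComparison:
    """Pointwise differences (b − a) and dominance flags."""

    table: pd.DataFrame
    acetate_lower_everywhere: bool
    growth_higher_everywhere: bool


def compare_scenarios(a: ScanResult, b: ScanResult,
                      tol: float = FLUX_ZERO_TOL) -> ScenarioComparison:
    """Compare two scans on identical grids (deltas are b − a)."""
    pa = [r.po for r in a.records]
    pb = [r.po for r in b.records]
    if pa != pb:
        raise ConfigurationError("scenario comparison requires identical grids")
    rows = []
    ac_lower = growth_higher = True
    for ra, rb in zip(a.records, b.records):
        if not (ra.feasible and rb.feasible):
            rows.append({"po": ra.po, "delta_mu": None,
                         "delta_q_ac": None, "delta_q_co2": None})
            continue
        d_mu = rb.growth_rate - ra.growth_rate
        d_ac = (rb.q_ac - ra.q_ac) if None not in (ra.q_ac, rb.q_ac) else None
        d_co2 = (rb.q_co2 - ra.q_co2) if None not in (ra.q_co2, rb.q_co2) else None
        rows.append({"po": ra.po, "delta_mu": d_mu,
                     "delta_q_ac": d_ac, "delta_q_co2": d_co2})
        if d_ac is not None and d_ac > tol:
            ac_lower = False
        if d_mu < -tol:
            growth_higher = False
    return ScenarioComparison(
        table=pd.DataFrame(rows),
        acetate_lower_everywhere=ac_lower,
        growth_higher_everywhere=growth_higher,
    )
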