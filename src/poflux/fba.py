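"""Flux balance analysis core: LP construction and solution.

FBA maximizes the objective flux c·v subject to steady state (S v = 0) and
per-reaction bounds lb ≤ v ≤ ub.  Parsimonious FBA (pFBA) resolves the
degeneracy of alternate optima by minimizing total absolute flux Σ|v| at
the fixed optimal objective, via the standard split-variable reformulation
v = v⁺ − v⁻.  Flux variability analysis (FVA) reports per-reaction flux
ranges at (a fraction of) the optimum.

All problems are solved with HiGHS through scipy.optimize.linprog, with
tightened feasibility tolerances and deterministic (sorted) row/column
ordering so repeated runs are bit-identical.  Every optimal solution is
re-verified against S v = 0 and the bounds independently of the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import SolverError
from .model import MetabolicModel

__all__ = [
    "LPProblem",
    "FluxSolution",
    "build_lp",
    "solve_fba",
    "solve_pfba",
    "fva",
    "FEASIBILITY_TOL",
    "FLUX_ZERO_TOL",
]

#: Max allowed ‖S·v‖∞ for an accepted optimal solution.
FEASIBILITY_TOL = 1e-8
#: Fluxes below this magnitude are treated as zero in diagnostics.
FLUX_ZERO_TOL = 1e-6
#: Bound violation slack accepted when certifying solutions.
BOUND_TOL = 1e-9

_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


@dataclass(frozen=True)
class LPProblem:
    """An FBA linear program in matrix form.

    Rows of ``S`` follow sorted metabolite ids, columns sorted reaction ids;
    ``c`` holds 1 on the objective reaction.  ``S v = 0`` is the only
    equality constraint.
    """

    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    reaction_ids: Tuple[str, ...]
    metabolite_ids: Tuple[str, ...]

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"reaction {reaction_id!r} not in LP") from None

    def with_bounds(self, reaction_id: str, lb: float, ub: float) -> "LPProblem":
        j = self.index(reaction_id)
        new_lb, new_ub = self.lb.copy(), self.ub.copy()
        new_lb[j], new_ub[j] = lb, ub
        return replace(self, lb=new_lb, ub=new_ub)


@dataclass
class FluxSolution:
    """One FBA/pFBA solution: status, objective and the full flux vector."""

    status: str  #: "optimal", "infeasible" or "unbounded"
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)
    total_absolute_flux: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_lp(model: MetabolicModel, objective_id: Optional[str] = None) -> LPProblem:
    """Assemble the stoichiometric LP from a model.

    Row/column order is deterministic (sorted ids).  Models carrying
    unresolved (NaN) coefficients — e.g. an ETC template whose P/O ratio
    has not been applied yet — are rejected.
    """
    if not model.reactions:
        raise ValueError("cannot build an LP from an empty model")
    objective_id = objective_id or model.objective_id
    if objective_id is None or objective_id not in model.reactions:
        raise ValueError(f"objective reaction {objective_id!r} not in model")

    unresolved = [r.id for r in model.reactions.values()
                  if r.has_unresolved_coefficients()]
    if unresolved:
        raise ValueError(
            "model has unresolved P/O-dependent coefficients in: "
            + ", ".join(sorted(unresolved)) + "; apply a P/O ratio first"
        )

    rids = tuple(sorted(model.reactions))
    mids = tuple(sorted({m for r in model.reactions.values() for m in r.stoich}))
    mindex = {m: i for i, m in enumerate(mids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rids):
        for met, coeff in model.reactions[rid].stoich.items():
            rows.append(mindex[met])
            cols.append(j)
            vals.append(coeff)
    S = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(mids), len(rids))
    ).tocsr()
    lb = np.array([model.reactions[r].lower_bound for r in rids], dtype=float)
    ub = np.array([model.reactions[r].upper_bound for r in rids], dtype=float)
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = 1.0
    return LPProblem(S=S, lb=lb, ub=ub, c=c,
                     reaction_ids=rids, metabolite_ids=mids)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _run_linprog(cost, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=dict(_SOLVER_OPTIONS))
    status = _STATUS.get(res.status, "error")
    if status in ("iteration_limit", "error"):
        raise SolverError(f"LP solver failed: {res.message}")
    return status, res


def _certify(lp: LPProblem, v: np.ndarray) -> None:
    residual = np.abs(lp.S @ v).max() if lp.S.shape[0] else 0.0
    if residual > FEASIBILITY_TOL:
        raise SolverError(
            f"solution violates steady state: ‖S·v‖∞ = {residual:.3e}"
        )
    if np.any(v < lp.lb - BOUND_TOL) or np.any(v > lp.ub + BOUND_TOL):
        raise SolverError("solution violates flux bounds")


def solve_fba(lp: LPProblem) -> FluxSolution:
    """Maximize c·v subject to S v = 0 and the bounds."""
    status, res = _run_linprog(
        -lp.c, lp.S, np.zeros(lp.S.shape[0]),
        np.column_stack([lp.lb, lp.ub]),
    )
    if status != "optimal":
        return FluxSolution(status=status)
    v = res.x
    _certify(lp, v)
    return FluxSolution(
        status="optimal",
        objective_value=float(lp.c @ v),
        fluxes=dict(zip(lp.reaction_ids, map(float, v))),
        total_absolute_flux=float(np.abs(v).sum()),
    )


def solve_pfba(lp: LPProblem, optimum: float) -> FluxSolution:
    """Minimize Σ|v| at the fixed FBA optimum c·v = *optimum*.

    Split-variable reformulation: v = v⁺ − v⁻ with v⁺, v⁻ ≥ 0 and
    min Σ(v⁺ + v⁻), which equals Σ|v| at the minimum.
    """
    n = len(lp.reaction_ids)
    S2 = sparse.hstack([lp.S, -lp.S], format="csr")
    obj_row = sparse.csr_matrix(np.concatenate([lp.c, -lp.c])[None, :])
    A_eq = sparse.vstack([S2, obj_row], format="csr")
    b_eq = np.zeros(lp.S.shape[0] + 1)
    b_eq[-1] = optimum
    lb2 = np.concatenate([np.maximum(lp.lb, 0.0), np.maximum(-lp.ub, 0.0)])
    ub2 = np.concatenate([np.maximum(lp.ub, 0.0), np.maximum(-lp.lb, 0.0)])
    status, res = _run_linprog(
        np.ones(2 * n), A_eq, b_eq, np.column_stack([lb2, ub2]),
    )
    if status != "optimal":
        return FluxSolution(status=status)
    v = res.x[:n] - res.x[n:]
    _certify(lp, v)
    return FluxSolution(
        status="optimal",
        objective_value=float(lp.c @ v),
        fluxes=dict(zip(lp.reaction_ids, map(float, v))),
        total_absolute_flux=float(np.abs(v).sum()),
    )


def fva(
    lp: LPProblem,
    reaction_ids: Sequence[str],
    fraction: float = 1.0,
    optimum: Optional[float] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux at ≥ *fraction* of the optimum.

    ``fraction`` must lie in (0, 1]; the optimum is computed if not given.
    Returns a dict reaction id → (min flux, max flux).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if optimum is None:
        sol = solve_fba(lp)
        if not sol.optimal:
            raise SolverError(f"FVA requires an optimal base solution, "
                              f"got status {sol.status!r}")
        optimum = sol.objective_value
    A_ub = sparse.csr_matrix(-lp.c[None, :])
    b_ub = np.array([-fraction * optimum])
    bounds = np.column_stack([lp.lb, lp.ub])
    zeros = np.zeros(lp.S.shape[0])
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in reaction_ids:
        j = lp.index(rid)
        cost = np.zeros(len(lp.reaction_ids))
        lo_hi = []
        for sign in (1.0, -1.0):
            cost[j] = sign
            status, res = _run_linprog(cost, lp.S, zeros, bounds,
                                       A_ub=A_ub, b_ub=b_ub)
            if status != "optimal":
                raise SolverError(f"FVA subproblem for {rid} returned {status}")
            lo_hi.append(sign * res.fun)
        ranges[rid] = (float(lo_hi[0]), float(lo_hi[1]))
    return ranges
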