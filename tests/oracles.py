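"""Independent brute-force oracles used to validate the LP machinery.

These deliberately avoid scipy.optimize: the flux polytope
P = {v : S v = 0, lb ≤ v ≤ ub} is searched by exhaustive vertex
enumeration with dense linear algebra, feasible for toy networks of up
to ~8 reactions.
"""

import itertools

import numpy as np


def enumerate_vertex_optimum(S, lb, ub, c, tol=1e-9):
    """Maximize c·v over the flux polytope by vertex enumeration.

    A vertex of {Sv = 0, lb ≤ v ≤ ub} fixes at least n − rank(S) fluxes at
    one of their bounds, with the remainder solving the square subsystem.
    All choices of fixed set and bound side are enumerated; the best
    feasible candidate is returned as (objective, v).  Returns (None, None)
    when the polytope is empty.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    best_obj, best_v = None, None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        choices = [(lb[j], ub[j]) if lb[j] != ub[j] else (lb[j],) for j in fixed]
        for vals in itertools.product(*choices):
            v = np.empty(n)
            for j, val in zip(fixed, vals):
                v[j] = val
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ np.asarray(vals) if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if S.size and np.abs(S @ v).max() > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            obj = float(c @ v)
            if best_obj is None or obj > best_obj:
                best_obj, best_v = obj, v.copy()
    return best_obj, best_v


def two_strategy_oxidase_totals(po, nadh=1.0, h_per_atp=4.0):
    """ATP yield per NADH for the two pure terminal-oxidase strategies.

    Routing one NADH through the translocating dehydrogenase (pumps 2P)
    and then either the bo oxidase (pumps 2P) or the bd oxidase (pumps P)
    gives 4P or 3P periplasmic protons, hence 4P/h or 3P/h ATP at the
    synthase.  Used to cross-check which oxidase pFBA should select.
    """
    bo = nadh * (2 * po + 2 * po) / h_per_atp
    bd = nadh * (2 * po + po) / h_per_atp
    return {"bo": bo, "bd": bd}
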