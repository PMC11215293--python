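"""Thin deterministic LP layer over scipy's HiGHS interface.

All solves in the package funnel through :func:`solve_lp` so that tolerances
and statuses are handled in one place.  Problems are maximization by
default (flux-balance convention); scipy minimizes, so the objective is
negated internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: primal feasibility / optimality tolerance passed to HiGHS
FEASIBILITY_TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None = None
    objective: float = float("nan")
    #: dual values of the A_ub rows (sign per scipy convention), if requested
    ineq_duals: np.ndarray | None = field(default=None, repr=False)

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    maximize: bool = True,
) -> LPResult:
    """Solve ``max/min c.x  s.t.  A_eq x = b_eq, A_ub x <= b_ub, bounds``.

    ``bounds`` is an ``(n, 2)`` array of per-variable (lower, upper); use
    ``None``/``inf`` entries for free variables.
    """
    c = np.asarray(c, dtype=float)
    obj = -c if maximize else c
    res = linprog(
        obj,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return LPResult(status=status)
    value = float(c @ res.x)
    duals = None
    if A_ub is not None and res.ineqlin is not None:
        duals = np.asarray(res.ineqlin.marginals, dtype=float)
        if maximize:
            # marginals are reported for the minimization problem
            duals = -duals
    return LPResult(status=OPTIMAL, x=np.asarray(res.x), objective=value, ineq_duals=duals)


def stack_eq(*blocks):
    """Vertically stack sparse equality blocks, skipping ``None``."""
    mats = [b for b in blocks if b is not None]
    if not mats:
        return None
    return sparse.vstack(mats, format="csr")
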