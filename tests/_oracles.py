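"""Independent oracles used to cross-check the solver and scoring paths.

These deliberately avoid the code paths they verify: LP optima are found
by brute-force enumeration of basic solutions, areas by the shoelace
formula, the front curve by an epsilon-constraint sweep (a different
algorithm from NISE), and hull volumes by Monte-Carlo membership tests
against hand-derived facet inequalities.
"""

from itertools import combinations, product

import numpy as np

from ecoscore import _lp
from ecoscore.molp import _equalities


def enumerate_lp_max(S, lb, ub, c, tol=1e-9):
    """Exhaustive maximum of c'v over {S v = 0, lb <= v <= ub}.

    Enumerates every basic solution (choice of rank(S) basic columns with
    the rest pinned at a bound) — exponential, fine for <= 10 reactions.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    best = -np.inf
    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        B = S[:, basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, pick in zip(nonbasic, choice):
                v[j] = ub[j] if pick else lb[j]
            rhs = -S[:, nonbasic] @ v[nonbasic]
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if np.max(np.abs(B @ sol - rhs)) > 1e-7:
                continue  # inconsistent basis
            v[list(basic)] = sol
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            best = max(best, float(c @ v))
    return best


def shoelace_area_under(points):
    """Signed area between an ordered polyline and the x axis (shoelace)."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, [pts[-1, 0], 0.0], [pts[0, 0], 0.0]])
    x, y = closed[:, 0], closed[:, 1]
    return -0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def epsilon_constraint_curve(eco, xs):
    """max f2 subject to f1 = x, for each grid value x (epsilon-constraint)."""
    ys = []
    bounds = np.column_stack([eco.lb, eco.ub])
    for x in xs:
        A, b = _equalities(eco, {0: float(x)})
        res = _lp.solve_lp(eco.C[1], A_eq=A, b_eq=b, bounds=bounds)
        if not res.optimal:
            raise RuntimeError(f"epsilon-constraint solve at f1={x}: {res.status}")
        ys.append(res.objective)
    return np.array(ys)


def pyramid_hull_membership(points):
    """Membership in conv{0, e1, e2, e3, (1,1,1)} from hand-derived facets.

    The hull is the set {x >= 0} cut by the three planes through (1,1,1)
    and two unit vectors: x_i + x_j - x_k <= 1 for each choice of k.
    """
    p = np.asarray(points, dtype=float)
    s = p.sum(axis=1)
    ok = np.all(p >= 0, axis=1)
    for k in range(3):
        ok &= (s - 2 * p[:, k]) <= 1 + 1e-12
    return ok


def monte_carlo_pyramid_volume(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    return float(pyramid_hull_membership(pts).mean())  # cube volume is 1
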