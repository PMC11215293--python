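"""Mono- and multi-objective linear programming over ecosystem models.

Provides flux balance analysis (FBA), flux variability analysis (FVA), and
exact Pareto-front vertex enumeration for the k-objective problem

    maximize (f_1, ..., f_k) = (c_1'v, ..., c_k'v)
    subject to  S_sigma v = 0,  l <= v <= u

For k = 2 the front is enumerated by NISE (non-inferior set estimation):
recursive weighted-sum bisection, exact for LPs.  For k >= 3 a
Benson-style outer approximation of the dominated region is refined with
supporting cuts obtained from LP duals until every vertex of the outer
polytope is attainable; the Pareto extreme points are read off its vertex
set.  A weighted-sum grid fallback is provided but is only approximate
(it can miss vertices lying on large optimal faces).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial import HalfspaceIntersection

from . import _lp
from .ecosystem import EcosystemModel

__all__ = [
    "FluxSolution",
    "ParetoFront",
    "UnboundedObjectiveError",
    "InfeasibleProblemError",
    "solve_fba",
    "solve_parsimonious",
    "solve_fva",
    "compute_pareto_front",
    "pareto_front_weighted_grid",
]

#: default merge tolerance for duplicate front vertices
VERTEX_TOL = 1e-6


class UnboundedObjectiveError(RuntimeError):
    pass


class InfeasibleProblemError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """One flux vector with per-member objective values."""

    status: str
    fluxes: np.ndarray | None = None
    objective_values: np.ndarray | None = None
    objective: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == _lp.OPTIMAL


@dataclass
class ParetoFront:
    """Non-dominated extreme points of the ecosystem objective space (raw units)."""

    dimension: int
    points: np.ndarray  # (n_points, k)
    organism_order: list[str]
    solver_tolerance: float = VERTEX_TOL

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.dimension == 2 and len(self.points) > 1:
            order = np.lexsort((-self.points[:, 1], self.points[:, 0]))
            self.points = self.points[order]

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.points, columns=self.organism_order)
        df.to_csv(path, sep="\t", index=False)
        meta = {
            "dimension": self.dimension,
            "organism_order": self.organism_order,
            "solver_tolerance": self.solver_tolerance,
            "n_points": int(len(self.points)),
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParetoFront":
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(
            dimension=meta["dimension"],
            points=df.to_numpy(),
            organism_order=meta["organism_order"],
            solver_tolerance=meta.get("solver_tolerance", VERTEX_TOL),
        )


# ---------------------------------------------------------------------------
# FBA / FVA


def _bounds_with_fixed(eco: EcosystemModel, fixed: dict[str, float] | None):
    lb = eco.lb.copy()
    ub = eco.ub.copy()
    if fixed:
        for rid, val in fixed.items():
            j = eco.reaction_index(rid)
            if val < lb[j] - 1e-9 or val > ub[j] + 1e-9:
                raise ValueError(
                    f"fixed value {val} for {rid!r} outside bounds [{lb[j]}, {ub[j]}]"
                )
            lb[j] = ub[j] = val
    return np.column_stack([lb, ub])


def _equalities(eco: EcosystemModel, objective_pins: dict[int, float] | None):
    """Steady-state rows plus optional member-objective equality pins."""
    A = eco.S
    b = np.zeros(A.shape[0])
    if objective_pins:
        rows = sparse.csr_matrix(
            np.array([eco.C[i] for i in sorted(objective_pins)])
        )
        A = sparse.vstack([A, rows], format="csr")
        b = np.concatenate([b, [objective_pins[i] for i in sorted(objective_pins)]])
    return A, b


def solve_fba(
    eco: EcosystemModel,
    objective_weights=None,
    fixed: dict[str, float] | None = None,
    objective_pins: dict[int, float] | None = None,
) -> FluxSolution:
    """Maximize the weighted sum of member objectives.

    ``fixed`` pins reaction fluxes (lb = ub = value); ``objective_pins``
    pins whole member objectives (equality rows c_i'v = value).  Infeasible
    and unbounded statuses are propagated, never clipped.
    """
    w = np.ones(eco.k) if objective_weights is None else np.asarray(objective_weights, float)
    if w.shape != (eco.k,) or not np.all(np.isfinite(w)):
        raise ValueError(f"objective_weights must be {eco.k} finite reals")
    c = w @ eco.C
    A, b = _equalities(eco, objective_pins)
    res = _lp.solve_lp(c, A_eq=A, b_eq=b, bounds=_bounds_with_fixed(eco, fixed))
    if not res.optimal:
        return FluxSolution(status=res.status)
    return FluxSolution(
        status=res.status,
        fluxes=res.x,
        objective_values=eco.C @ res.x,
        objective=res.objective,
    )


def solve_parsimonious(
    eco: EcosystemModel,
    objective_pins: dict[int, float],
    fixed: dict[str, float] | None = None,
) -> FluxSolution:
    """Minimize total absolute flux subject to pinned member objectives.

    Deterministic representative of the (generally under-determined) flux
    space at a front point; the LP splits |v| with auxiliary variables.
    """
    n = eco.n_bar
    A, b = _equalities(eco, objective_pins)
    # variables z = (v, t); minimize sum t, with t >= v and t >= -v
    A_eq = sparse.hstack([A, sparse.csr_matrix((A.shape[0], n))], format="csr")
    eye = sparse.identity(n, format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])], format="csr"
    )
    b_ub = np.zeros(2 * n)
    vb = _bounds_with_fixed(eco, fixed)
    cap = max(eco.flux_cap, float(np.abs(vb).max()))
    tb = np.column_stack([np.zeros(n), np.full(n, cap)])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = _lp.solve_lp(
        c, A_eq=A_eq, b_eq=b, A_ub=A_ub, b_ub=b_ub,
        bounds=np.vstack([vb, tb]), maximize=False,
    )
    if not res.optimal:
        return FluxSolution(status=res.status)
    v = res.x[:n]
    return FluxSolution(
        status=res.status, fluxes=v, objective_values=eco.C @ v,
        objective=float(np.sum(np.abs(v))),
    )


def solve_fva(
    eco: EcosystemModel,
    reactions=None,
    fixed: dict[str, float] | None = None,
    objective_pins: dict[int, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to constraints and pins."""
    if reactions is None:
        reactions = eco.reaction_ids
    A, b = _equalities(eco, objective_pins)
    bounds = _bounds_with_fixed(eco, fixed)
    out: dict[str, tuple[float, float]] = {}
    n = eco.n_bar
    for rid in reactions:
        j = eco.reaction_index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo = _lp.solve_lp(c, A_eq=A, b_eq=b, bounds=bounds, maximize=False)
        hi = _lp.solve_lp(c, A_eq=A, b_eq=b, bounds=bounds, maximize=True)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleProblemError(
                f"FVA for {rid!r}: {lo.status}/{hi.status} under the given pins"
            )
        out[rid] = (lo.objective, hi.objective)
    return out


# ---------------------------------------------------------------------------
# Pareto front enumeration


def _points_close(p, q, tol=VERTEX_TOL) -> bool:
    p = np.asarray(p)
    q = np.asarray(q)
    return float(np.max(np.abs(p - q))) < tol * (1.0 + float(np.max(np.abs(p))))


def _dedupe(points, tol=VERTEX_TOL):
    kept: list[np.ndarray] = []
    for p in points:
        if not any(_points_close(p, q, tol) for q in kept):
            kept.append(np.asarray(p, float))
    return kept


def _nondominated(points, tol=1e-9):
    pts = [np.asarray(p, float) for p in points]
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if i == j:
                continue
            if np.all(q >= p - tol) and np.any(q > p + 10 * tol):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    return keep


def _check_bounded(eco: EcosystemModel, i: int, res: _lp.LPResult) -> None:
    if res.status == _lp.UNBOUNDED:
        raise UnboundedObjectiveError(
            f"objective of member {eco.member_ids[i]!r} is unbounded; constrain "
            "the diet or rely on the transport flux cap"
        )
    if res.status != _lp.OPTIMAL:
        raise InfeasibleProblemError(
            f"pre-solve for member {eco.member_ids[i]!r}: {res.status}"
        )


def _lex_max(eco: EcosystemModel, order, bounds, A, b):
    """Lexicographic maximization of member objectives in ``order``.

    Returns the objective vector of a vertex of the image polytope that is
    lexicographically optimal — used for NISE endpoints and anchor points.
    """
    A_cur, b_cur = A, b.copy()
    x = None
    for pos, i in enumerate(order):
        res = _lp.solve_lp(eco.C[i], A_eq=A_cur, b_eq=b_cur, bounds=bounds)
        _check_bounded(eco, i, res)
        x = res.x
        if pos < len(order) - 1:
            A_cur = sparse.vstack([A_cur, sparse.csr_matrix(eco.C[i])], format="csr")
            b_cur = np.concatenate([b_cur, [res.objective]])
    return eco.C @ x


def _nise(eco: EcosystemModel, tol: float) -> list[np.ndarray]:
    A, b = eco.S, np.zeros(eco.S.shape[0])
    bounds = np.column_stack([eco.lb, eco.ub])
    right = _lex_max(eco, (0, 1), bounds, A, b)  # max f0, then f1
    left = _lex_max(eco, (1, 0), bounds, A, b)  # max f1, then f0
    if _points_close(left, right, tol):
        return [right]

    points = [left, right]

    def refine(a: np.ndarray, c: np.ndarray) -> None:
        # a left of c (a[0] < c[0]); chord outward normal, both components >= 0
        w = np.array([a[1] - c[1], c[0] - a[0]])
        scale = float(np.max(np.abs(w)))
        if scale <= 0:
            return
        w = w / scale
        obj = w @ eco.C
        res = _lp.solve_lp(obj, A_eq=A, b_eq=b, bounds=bounds)
        if not res.optimal:
            raise InfeasibleProblemError(f"NISE weighted solve failed: {res.status}")
        chord_val = float(w @ a)
        if res.objective <= chord_val + tol * (1.0 + abs(chord_val)):
            return
        # land on a vertex of the optimal face: fix w'f, maximize f0
        A2 = sparse.vstack([A, sparse.csr_matrix(obj)], format="csr")
        b2 = np.concatenate([b, [res.objective]])
        res2 = _lp.solve_lp(eco.C[0], A_eq=A2, b_eq=b2, bounds=bounds)
        z = eco.C @ (res2.x if res2.optimal else res.x)
        if _points_close(z, a, tol) or _points_close(z, c, tol):
            return
        points.append(z)
        refine(a, z)
        refine(z, c)

    refine(left, right)
    return _dedupe(points, tol)


def _membership(eco, y, A_eq_ext, b_eq, bounds_ext, tol):
    """Max t with C v - t >= y; returns (t*, dual weights on the k rows)."""
    k, n = eco.C.shape
    A_ub = np.hstack([-eco.C, np.ones((k, 1))])
    c = np.zeros(n + 1)
    c[-1] = 1.0
    res = _lp.solve_lp(
        c, A_eq=A_eq_ext, b_eq=b_eq, A_ub=A_ub, b_ub=-np.asarray(y, float),
        bounds=bounds_ext,
    )
    if not res.optimal:
        raise InfeasibleProblemError(f"Benson membership solve failed: {res.status}")
    lam = np.clip(res.ineq_duals, 0.0, None) if res.ineq_duals is not None else None
    return res.objective, lam


def _benson(eco: EcosystemModel, tol: float, max_rounds: int = 200) -> list[np.ndarray]:
    """Outer approximation of the dominated region P = {y : y <= Cv feasible}.

    P is intersected with a strict lower box so the working polytope is
    always full-dimensional even when the front itself is degenerate
    (e.g., a single ideal point).  Vertices of the final polytope that do
    not touch the lower box are exactly the Pareto extreme points.
    """
    k = eco.k
    A, b = eco.S, np.zeros(eco.S.shape[0])
    bounds = np.column_stack([eco.lb, eco.ub])

    ideal = np.empty(k)
    floor = np.empty(k)
    for i in range(k):
        hi = _lp.solve_lp(eco.C[i], A_eq=A, b_eq=b, bounds=bounds)
        _check_bounded(eco, i, hi)
        ideal[i] = hi.objective
        lo = _lp.solve_lp(eco.C[i], A_eq=A, b_eq=b, bounds=bounds, maximize=False)
        floor[i] = lo.objective if lo.optimal else -eco.flux_cap * k
    L = floor - 1.0 - 0.05 * (ideal - floor)

    # halfspaces a.y <= rhs
    normals = [row for row in np.eye(k)] + [-row for row in np.eye(k)]
    offsets = list(ideal) + list(-L)

    bounds_ext = np.vstack([bounds, [[-np.inf, np.inf]]])
    A_eq_ext = sparse.hstack([A, sparse.csr_matrix((A.shape[0], 1))], format="csr")

    verified: set[tuple] = set()
    vertices: list[np.ndarray] = []
    for _ in range(max_rounds):
        vertices = _polytope_vertices(np.array(normals), np.array(offsets))
        added = False
        for y in vertices:
            key = tuple(np.round(y / (1.0 + np.abs(y)), 7))
            if key in verified:
                continue
            t, lam = _membership(eco, y, A_eq_ext, b, bounds_ext, tol)
            if t >= -tol * (1.0 + float(np.max(np.abs(y)))):
                verified.add(key)
                continue
            if lam is None or lam.sum() <= 0:
                lam = np.ones(k)
            w = lam / lam.sum()
            sup = _lp.solve_lp(w @ eco.C, A_eq=A, b_eq=b, bounds=bounds)
            if not sup.optimal:
                raise InfeasibleProblemError(f"Benson support solve: {sup.status}")
            if w @ y <= sup.objective + tol:
                # degenerate dual; fall back to a slightly mixed weight
                w = 0.9 * w + 0.1 / k
                sup = _lp.solve_lp(w @ eco.C, A_eq=A, b_eq=b, bounds=bounds)
                if w @ y <= sup.objective + tol:
                    verified.add(key)
                    continue
            normals.append(w)
            offsets.append(sup.objective)
            added = True
        if not added:
            break
    else:
        raise RuntimeError("Benson outer approximation did not converge")

    front = [
        y for y in vertices if np.all(y > L + 1e-6 * (1.0 + np.abs(L)))
    ]
    return _dedupe(_nondominated(front), tol)


def _polytope_vertices(Ah: np.ndarray, bh: np.ndarray) -> list[np.ndarray]:
    """Vertices of {y : Ah y <= bh} via qhull, from a Chebyshev center."""
    norms = np.linalg.norm(Ah, axis=1)
    k = Ah.shape[1]
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([Ah, norms[:, None]]),
        b_ub=bh,
        bounds=[(None, None)] * k + [(0, None)],
        method="highs",
    )
    if res.status != 0 or res.x[-1] <= 1e-12:
        raise RuntimeError("outer polytope has no interior")
    interior = res.x[:k]
    hs = HalfspaceIntersection(np.hstack([Ah, -bh[:, None]]), interior)
    return _dedupe(list(hs.intersections), 1e-7)


def compute_pareto_front(
    eco: EcosystemModel, tol: float = VERTEX_TOL, method: str | None = None
) -> ParetoFront:
    """Enumerate the Pareto-front extreme points of the ecosystem problem.

    ``method`` defaults to NISE for two objectives and Benson-style outer
    approximation for three or more; ``"weighted_grid"`` selects the
    approximate fallback.
    """
    if method == "weighted_grid":
        return pareto_front_weighted_grid(eco, tol=tol)
    k = eco.k
    A, b = eco.S, np.zeros(eco.S.shape[0])
    bounds = np.column_stack([eco.lb, eco.ub])
    if k == 1:
        pt = _lex_max(eco, (0,), bounds, A, b)
        return ParetoFront(1, [pt], eco.member_ids, tol)
    if k == 2:
        pts = _nise(eco, tol)
    else:
        pts = _benson(eco, tol)
    return ParetoFront(k, np.array(pts), eco.member_ids, tol)


def pareto_front_weighted_grid(
    eco: EcosystemModel, n_weights: int = 10, tol: float = VERTEX_TOL
) -> ParetoFront:
    """Approximate front by solving a simplex grid of weighted sums.

    Finds only vertices that are unique optima of some sampled weight; a
    vertex interior to a sampled face's optimum set can be missed.  Exact
    enumeration (:func:`compute_pareto_front`) is preferred.
    """
    k = eco.k
    A, b = eco.S, np.zeros(eco.S.shape[0])
    bounds = np.column_stack([eco.lb, eco.ub])
    pts = []
    for comb in itertools.combinations_with_replacement(range(k), n_weights):
        w = np.bincount(comb, minlength=k).astype(float)
        if np.count_nonzero(w) == 0:
            continue
        res = _lp.solve_lp(w @ eco.C, A_eq=A, b_eq=b, bounds=bounds)
        if res.status == _lp.UNBOUNDED:
            i = int(np.argmax(w))
            _check_bounded(eco, i, res)
        if res.optimal:
            pts.append(eco.C @ res.x)
    pts = _dedupe(_nondominated(pts), tol)
    return ParetoFront(k, np.array(pts), eco.member_ids, tol)
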