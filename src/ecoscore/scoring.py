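"""Interaction score and interaction-type calls from Pareto fronts.

The front is first normalized axis-by-axis by each member's optimum when
it grows *alone* under the same diet (with the full pool to itself); the
"original growth points" — the k unit vectors — are appended.  The
interaction score is then

    S = AUC_P - AUC_NI            (two members)
    S = HV_P  - HV_NI             (three or more members)

where AUC_P is the area under the augmented normalized front, AUC_NI = 1
is the area under the non-interaction front through (0,1), (1,1), (1,0),
and the hypervolumes are convex-hull volumes of the augmented point set
plus the origin (HV_NI uses the neutral front: the all-ones point).  A
positive S indicates mutualistic trade-offs, zero neutrality, negative
competition.

In two dimensions the front's shape is further discretized into six
interaction types from four boolean conditions (sign of S; whether either
organism can exceed its alone optimum; whether one solution attains both
organisms' best values simultaneously).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .ecosystem import DietSpec, EcosystemModel, apply_diet, build_ecosystem, read_diet, remove_member
from .model_io import read_model
from .molp import ParetoFront, compute_pareto_front, solve_fba

__all__ = [
    "NormalizedFront",
    "InteractionReport",
    "ZeroAloneGrowthError",
    "alone_maxima",
    "normalize_front",
    "auc_2d",
    "hypervolume",
    "interaction_score",
    "classify_interaction",
    "removal_analysis",
    "score_ecosystem",
]

INTERACTION_TYPES = (
    "Neutralism",
    "Competition",
    "FavorsHost",
    "FavorsBacteria",
    "LimitedMutualism",
    "Mutualism",
    "Unclassified",
)

#: (sign, E+, B+, E+B+) -> interaction type; anything else is Unclassified
_TYPE_TABLE = {
    ("+", False, False, False): "Neutralism",
    ("-", False, False, False): "Competition",
    ("+", True, False, False): "FavorsHost",
    ("+", False, True, False): "FavorsBacteria",
    ("+", True, True, False): "LimitedMutualism",
    ("+", True, True, True): "Mutualism",
}

DEFAULT_TOL = 1e-6


class ZeroAloneGrowthError(RuntimeError):
    pass


@dataclass
class NormalizedFront:
    """Front points divided by alone-growth maxima, plus the unit vectors."""

    base: ParetoFront
    alone_maxima: np.ndarray
    points: np.ndarray  # normalized front points, (n, k)
    augmented_points: np.ndarray  # points + unit vectors (each exactly once)
    organism_order: list[str]

    @property
    def dimension(self) -> int:
        return self.base.dimension


@dataclass
class InteractionReport:
    score: float
    auc_p: float
    auc_ni: float
    sign: str = "+"
    e_plus: bool = False
    b_plus: bool = False
    eb_plus: bool = False
    interaction_type: str = "Unclassified"
    organism_order: list[str] = field(default_factory=list)
    alone_maxima: list[float] = field(default_factory=list)
    front_points: list[list[float]] = field(default_factory=list)
    removal_scores: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "score": self.score,
            "auc_pareto": self.auc_p,
            "auc_non_interaction": self.auc_ni,
            "flags": {
                "sign": self.sign,
                "E_plus": self.e_plus,
                "B_plus": self.b_plus,
                "EB_plus": self.eb_plus,
            },
            "interaction_type": self.interaction_type,
            "organism_order": self.organism_order,
            "alone_maxima": self.alone_maxima,
            "front_points": self.front_points,
        }
        if self.removal_scores is not None:
            out["removal_scores"] = self.removal_scores
        return out

    def summary(self) -> str:
        lines = [
            f"members           : {', '.join(self.organism_order)}",
            f"interaction score : {self.score:+.6g}",
            f"interaction type  : {self.interaction_type}",
            f"front points      : {len(self.front_points)}",
            f"alone maxima      : {np.array2string(np.asarray(self.alone_maxima), precision=4)}",
            f"flags             : sign={self.sign} E+={self.e_plus} B+={self.b_plus} E+B+={self.eb_plus}",
        ]
        if self.removal_scores:
            lines.append("removal scores (k-1 dimensional, not comparable across k):")
            for mid, s in self.removal_scores.items():
                lines.append(f"  - without {mid}: {s:+.6g}")
        return "\n".join(lines)


def alone_maxima(
    eco: EcosystemModel, diet: DietSpec | None = None, tol: float = DEFAULT_TOL
) -> np.ndarray:
    """Each member's optimum alone (own pool, same diet) in member order."""
    diet = diet or eco.diet
    out = np.empty(eco.k)
    for i, member in enumerate(eco.members):
        solo = build_ecosystem([member], flux_cap=eco.flux_cap)
        if diet is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                solo = apply_diet(solo, diet)
        sol = solve_fba(solo, [1.0])
        if not sol.optimal:
            raise ZeroAloneGrowthError(
                f"standalone solve for {member.model_id!r}: {sol.status}"
            )
        out[i] = sol.objective
        if out[i] <= tol:
            raise ZeroAloneGrowthError(
                f"score undefined: zero standalone growth for {member.model_id!r}"
            )
    return out


def normalize_front(
    front: ParetoFront,
    eco: EcosystemModel,
    diet: DietSpec | None = None,
    tol: float = DEFAULT_TOL,
) -> NormalizedFront:
    """Normalize each axis by the member's alone optimum and append the
    original-growth unit vectors."""
    alone = alone_maxima(eco, diet, tol)
    pts = front.points / alone
    k = front.dimension
    aug = list(pts)
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        if not any(np.max(np.abs(p - e)) < tol for p in aug):
            aug.append(e)
    return NormalizedFront(
        base=front,
        alone_maxima=alone,
        points=pts,
        augmented_points=np.array(aug),
        organism_order=list(front.organism_order),
    )


def auc_2d(points) -> float:
    """Trapezoidal area under an ordered 2-D front polyline.

    The front may reverse direction only at its final segment (the added
    (1,0) point when the front extends past x = 1); that last trapezoid is
    then subtracted from the area of the monotone prefix.  An interior
    reversal is an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("auc_2d needs at least two points")
    dx = np.diff(pts[:, 0])
    if np.any(dx[:-1] < 0):
        raise ValueError("front is non-monotonic before its last point")
    heights = (pts[:-1, 1] + pts[1:, 1]) / 2.0
    if dx[-1] < 0:
        return float(np.sum(dx[:-1] * heights[:-1]) - (-dx[-1]) * heights[-1])
    return float(np.sum(dx * heights))


def hypervolume(points) -> float:
    """Convex-hull volume of a k-D point set (0 for rank-deficient hulls)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = pts.shape[1]
    if k < 2:
        raise ValueError("hypervolume needs dimension >= 2")
    if len(pts) <= k:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0  # degenerate (flat) point set


def _ordered_curve(nf: NormalizedFront, tol: float = DEFAULT_TOL) -> np.ndarray:
    """(0,1) + front sorted ascending in x + (1,0), duplicates merged."""
    pts = [np.array([0.0, 1.0])]
    front = nf.points[np.lexsort((-nf.points[:, 1], nf.points[:, 0]))]
    for p in front:
        if np.max(np.abs(p - pts[-1])) > tol:
            pts.append(p)
    last = np.array([1.0, 0.0])
    if np.max(np.abs(last - pts[-1])) > tol:
        pts.append(last)
    return np.array(pts)


def interaction_score(nf: NormalizedFront, tol: float = DEFAULT_TOL) -> InteractionReport:
    """Compute S (and its components) from a normalized front."""
    k = nf.dimension
    if k == 2:
        auc_p = auc_2d(_ordered_curve(nf, tol))
        auc_ni = 1.0  # unit square under the neutral front (0,1)-(1,1)-(1,0)
    else:
        origin = np.zeros(k)
        pts = np.vstack([nf.augmented_points, origin])
        auc_p = hypervolume(pts)
        neutral = np.vstack([origin, np.eye(k), np.ones(k)])
        auc_ni = hypervolume(neutral)
    report = InteractionReport(
        score=auc_p - auc_ni,
        auc_p=auc_p,
        auc_ni=auc_ni,
        organism_order=list(nf.organism_order),
        alone_maxima=[float(a) for a in nf.alone_maxima],
        front_points=[[float(x) for x in p] for p in nf.points],
    )
    if k == 2:
        report = classify_interaction(nf, report, tol)
    return report


def classify_interaction(
    nf: NormalizedFront, report: InteractionReport, tol: float = DEFAULT_TOL
) -> InteractionReport:
    """Fill the shape flags and six-way interaction type (two members only).

    E+ (B+): some front point exceeds the first (second) member's alone
    optimum.  E+B+: a single front point attains both members' best values
    over the front simultaneously.  A score within ``tol`` of zero counts
    as "+" so pure neutrality classifies as Neutralism.
    """
    if nf.dimension != 2:
        raise ValueError("interaction types are defined for two-member ecosystems only")
    pts = nf.points
    report.e_plus = bool(np.any(pts[:, 0] > 1.0 + tol))
    report.b_plus = bool(np.any(pts[:, 1] > 1.0 + tol))
    best = pts.max(axis=0)
    simultaneous = np.any(
        np.all(pts >= best - tol * (1.0 + np.abs(best)), axis=1)
    )
    report.eb_plus = bool(report.e_plus and report.b_plus and simultaneous)
    report.sign = "-" if report.score < -tol else "+"
    key = (report.sign, report.e_plus, report.b_plus, report.eb_plus)
    report.interaction_type = _TYPE_TABLE.get(key, "Unclassified")
    return report


def score_front(
    eco: EcosystemModel, diet: DietSpec | None = None, tol: float = DEFAULT_TOL
) -> InteractionReport:
    """Front -> normalize -> score (+classify when k = 2) for one ecosystem."""
    front = compute_pareto_front(eco, tol=tol)
    nf = normalize_front(front, eco, diet, tol)
    return interaction_score(nf, tol)


def removal_analysis(
    eco: EcosystemModel, diet: DietSpec | None = None, tol: float = DEFAULT_TOL
) -> dict[str, float]:
    """Score of each (k-1)-member ecosystem after removing one member.

    Scores of different dimensionality are *not* mathematically comparable
    across k; they are reported to rank the members' contributions within
    one ecosystem.
    """
    if eco.k < 3:
        raise ValueError("removal analysis needs at least three members")
    if diet is not None and eco.diet is None:
        eco = apply_diet(eco, diet)
    scores: dict[str, float] = {}
    for member in eco.member_ids:
        reduced = remove_member(eco, member)
        scores[member] = score_front(reduced, eco.diet, tol).score
    return scores


def score_ecosystem(
    model_paths,
    diet_path=None,
    removal: bool = False,
    tol: float = DEFAULT_TOL,
    exchange_policy: str = "boundary",
) -> InteractionReport:
    """End-to-end pipeline: read models, assemble, constrain, score.

    Deterministic: repeated runs on the same inputs give identical reports.
    """
    paths = [Path(p) for p in model_paths]
    if len(paths) < 2:
        raise ValueError("scoring needs at least two member models")
    try:
        members = [read_model(p) for p in paths]
    except Exception as exc:
        raise RuntimeError(f"[stage: read models] {exc}") from exc
    try:
        eco = build_ecosystem(members, exchange_policy=exchange_policy)
    except Exception as exc:
        raise RuntimeError(f"[stage: build ecosystem] {exc}") from exc
    diet = None
    if diet_path is not None:
        try:
            diet = read_diet(diet_path)
            eco = apply_diet(eco, diet)
        except Exception as exc:
            raise RuntimeError(f"[stage: apply diet] {exc}") from exc
    try:
        report = score_front(eco, diet, tol)
    except Exception as exc:
        raise RuntimeError(f"[stage: score] {exc}") from exc
    if removal and eco.k >= 3:
        report.removal_scores = removal_analysis(eco, diet, tol)
    return report
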