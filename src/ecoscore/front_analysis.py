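"""Sampling along a bi-objective Pareto front and flux–biomass correlation.

Solutions are sampled at pinned objective pairs placed along the front;
each sample is one FBA solve with both member objectives fixed, by default
resolved to the parsimonious (minimum total absolute flux) representative
since the flux space at a pinned point is generally under-determined.
Spearman correlations of transport-reaction (and host blood) fluxes
against the ecosystem biomass (the sum of the pinned objectives) flag
driver metabolites; correlated secretion/uptake flux pairs across members
flag exchanged (cross-fed) metabolites; FVA intervals excluding zero at a
pinned point flag obligatory reactions.

Sample placement: the default ``"boundary"`` mode sweeps the attainable
upper boundary of the objective region — an arc-length-uniform grid of
first-objective values, each paired with the constrained maximum of the
second objective.  Between front vertices this boundary *is* the front
polyline (the image of an LP is polyhedral), and it extends through
single-point ("spike") fronts where the strict vertex set is degenerate.
``"polyline"`` places samples on the augmented front polyline through the
alone-growth endpoints instead (the dotted-line traversal of the front
figure), which for spike fronts includes a descending leg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ecosystem import EcosystemModel
from .molp import ParetoFront, solve_fba, solve_fva, solve_parsimonious
from .scoring import alone_maxima

__all__ = [
    "FluxSampleMatrix",
    "DriverReport",
    "sample_front",
    "correlate_drivers",
    "find_exchanged",
    "find_obligatory",
]

DRIVER_THRESHOLD = 0.95  # |Spearman rho| flagging a driver exchange flux
PAIRING_THRESHOLD = 0.5  # Spearman rho pairing secretion with uptake
DEFAULT_N_SAMPLES = 100_000


@dataclass
class FluxSampleMatrix:
    """Fluxes of sampled front solutions plus the ecosystem-biomass column."""

    samples: pd.DataFrame  # (n_samples, n_bar), columns = ecosystem reaction ids
    front_points: np.ndarray  # (n_samples, k) pinned objective values
    ecosystem_biomass: np.ndarray  # (n_samples,) = rowwise sum of pins

    def __len__(self) -> int:
        return len(self.samples)

    def to_tsv(self, path: str | Path) -> None:
        df = self.samples.copy()
        df.insert(0, "ecosystem_biomass", self.ecosystem_biomass)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DriverReport:
    #: (reaction_id, metabolite_id, member_id, direction, rho)
    drivers: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    #: (metabolite_id, producer_id, consumer_id, rho_pair)
    exchanged: list[tuple[str, str, str, float]] = field(default_factory=list)
    obligatory: set[str] = field(default_factory=set)
    skipped: list[str] = field(default_factory=list)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "drivers": pd.DataFrame(
                self.drivers,
                columns=["reaction_id", "metabolite_id", "member_id", "direction", "rho"],
            ),
            "exchanged": pd.DataFrame(
                self.exchanged,
                columns=["metabolite_id", "producer_id", "consumer_id", "rho_pair"],
            ),
            "obligatory": pd.DataFrame({"reaction_id": sorted(self.obligatory)}),
        }


def _transport_table(eco: EcosystemModel) -> list[tuple[str, str, str]]:
    """(ecosystem reaction id, member id, pool metabolite id) for every TR."""
    members = {m.model_id: m for m in eco.members}
    out = []
    for (member_id, ex_id), rid in eco.transport_reactions.items():
        (mid,) = members[member_id].reactions[ex_id].stoichiometry
        out.append((rid, member_id, mid))
    return out


def _polyline_points(vertices: np.ndarray, n: int) -> np.ndarray:
    """n arc-length-uniform points along a polyline (endpoints included)."""
    seg = np.diff(vertices, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if lengths.sum() <= 0:
        return np.repeat(vertices[:1], n, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    stations = np.linspace(0.0, cum[-1], n)
    pts = np.empty((n, vertices.shape[1]))
    for row, s in enumerate(stations):
        i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg) - 1)
        t = (s - cum[i]) / lengths[i] if lengths[i] > 0 else 0.0
        pts[row] = vertices[i] + t * seg[i]
    return pts


def sample_front(
    eco: EcosystemModel,
    front: ParetoFront,
    n: int = DEFAULT_N_SAMPLES,
    secondary: str = "min_total_flux",
    placement: str = "boundary",
) -> FluxSampleMatrix:
    """Sample ``n`` solutions at pinned objective pairs along the front.

    ``secondary="min_total_flux"`` picks the parsimonious flux vector at
    each pin (deterministic); ``"none"`` accepts an arbitrary optimal
    basis.  Numerically infeasible pins are nudged inward once (1e-9
    relative) and dropped with a warning if still infeasible.
    """
    if front.dimension != 2:
        raise ValueError("front sampling is defined for bi-objective fronts")
    if n < 2:
        raise ValueError("need at least two samples")
    if secondary not in ("min_total_flux", "none"):
        raise ValueError(f"unknown secondary objective {secondary!r}")

    verts = front.points[np.argsort(front.points[:, 0])]
    if placement == "boundary":
        pins = _boundary_pins(eco, verts, n)
    elif placement == "polyline":
        alone = alone_maxima(eco)
        chain = [np.array([0.0, alone[1]])] if verts[0, 0] > 1e-9 else []
        chain += list(verts)
        if verts[-1, 1] > 1e-9:
            chain.append(np.array([alone[0], 0.0]))
        pins = _polyline_points(np.array(chain), n)
    else:
        raise ValueError(f"unknown placement {placement!r}")

    rows, kept_pins = [], []
    for pin in pins:
        sol = _pinned_solution(eco, pin, secondary)
        if sol is None:
            inner = pin * (1.0 - 1e-9)
            sol = _pinned_solution(eco, inner, secondary)
            if sol is None:
                warnings.warn(f"dropping infeasible front pin {pin}", stacklevel=2)
                continue
            pin = inner
        rows.append(sol)
        kept_pins.append(pin)
    if len(rows) < 2:
        raise RuntimeError("fewer than two feasible samples along the front")
    pins_arr = np.array(kept_pins)
    return FluxSampleMatrix(
        samples=pd.DataFrame(np.array(rows), columns=eco.reaction_ids),
        front_points=pins_arr,
        ecosystem_biomass=pins_arr.sum(axis=1),
    )


def _boundary_pins(eco: EcosystemModel, verts: np.ndarray, n: int) -> np.ndarray:
    """Arc-length-uniform pins on the coupled part of the upper boundary.

    The strict front polyline is extended with a rising approach arc —
    from the attainable minimum of one objective up to the front — only
    where the constrained maximum of the other objective *increases*
    along it (positive coupling; a spike front's dotted ascent).  Flat
    approaches (the other member is insensitive there) carry no
    interaction signal and are not sampled, so a strictly neutral front
    yields constant flux columns.  Both axis orientations are checked.
    """
    tol = 1e-6 * (1.0 + float(np.max(np.abs(verts))))
    guide = verts
    swept_axis = 0
    x_lo = _objective_extreme(eco, 0, maximize=False)
    if x_lo < verts[0, 0] - tol:
        y_at_lo = _objective_extreme(eco, 1, maximize=True, pin=(0, x_lo))
        if y_at_lo < verts[0, 1] - tol:  # rising approach: coupling present
            guide = np.vstack([[x_lo, y_at_lo], verts])
    if len(guide) == 1:
        # degenerate in the x orientation; try the y orientation
        y_lo = _objective_extreme(eco, 1, maximize=False)
        if y_lo < verts[-1, 1] - tol:
            x_at_lo = _objective_extreme(eco, 0, maximize=True, pin=(1, y_lo))
            if x_at_lo < verts[-1, 0] - tol:
                guide = np.vstack([[x_at_lo, y_lo], verts[::-1]])
                swept_axis = 1
    targets = _polyline_points(guide, n)
    pins = np.empty_like(targets)
    free_axis = 1 - swept_axis
    for i, target in enumerate(targets):
        pinned_val = float(target[swept_axis])
        other = _objective_extreme(
            eco, free_axis, maximize=True, pin=(swept_axis, pinned_val)
        )
        pins[i, swept_axis] = pinned_val
        pins[i, free_axis] = other
    return pins


def _objective_extreme(eco, i, maximize, pin=None):
    from . import _lp
    from .molp import _equalities

    pins = {pin[0]: pin[1]} if pin is not None else None
    A, b = _equalities(eco, pins)
    res = _lp.solve_lp(
        eco.C[i], A_eq=A, b_eq=b,
        bounds=np.column_stack([eco.lb, eco.ub]), maximize=maximize,
    )
    if not res.optimal:
        raise RuntimeError(f"objective extreme solve failed: {res.status}")
    return float(res.objective)


def _pinned_solution(eco, pin, secondary):
    pins = {0: float(pin[0]), 1: float(pin[1])}
    if secondary == "min_total_flux":
        sol = solve_parsimonious(eco, pins)
    else:
        sol = solve_fba(eco, np.zeros(eco.k), objective_pins=pins)
    return sol.fluxes if sol.optimal else None


def correlate_drivers(
    fsm: FluxSampleMatrix,
    eco: EcosystemModel,
    threshold: float = DRIVER_THRESHOLD,
) -> DriverReport:
    """Flag transport (and host blood) fluxes tracking ecosystem biomass.

    Spearman rho >= +threshold: the metabolite's release grows with
    ecosystem biomass ("secreted" driver); rho <= -threshold: its uptake
    grows with biomass ("uptaken" driver, negative flux = uptake).
    Constant flux columns have no defined rank correlation and are
    skipped.
    """
    if len(fsm) < 3:
        raise ValueError("need at least three distinct samples")
    report = DriverReport()
    biomass = fsm.ecosystem_biomass
    if np.ptp(biomass) < 1e-12:
        # constant ecosystem biomass (e.g. a pure-competition front):
        # no flux can rank-correlate with it
        report.skipped.append("ecosystem_biomass (constant)")
        return report
    columns = list(_transport_table(eco))
    for member_id, rids in eco.blood_reactions.items():
        for rid in rids:
            bare = rid.split(":", 1)[1]
            (mid,) = next(
                m for m in eco.members if m.model_id == member_id
            ).reactions[bare].stoichiometry
            columns.append((rid, member_id, mid))
    for rid, member_id, mid in columns:
        flux = fsm.samples[rid].to_numpy()
        if np.ptp(flux) < 1e-12:
            report.skipped.append(rid)
            continue
        rho = float(spearmanr(flux, biomass).statistic)
        if rho >= threshold:
            report.drivers.append((rid, mid, member_id, "secreted", rho))
        elif rho <= -threshold:
            report.drivers.append((rid, mid, member_id, "uptaken", rho))
    return report


def find_exchanged(
    fsm: FluxSampleMatrix,
    eco: EcosystemModel,
    threshold: float = PAIRING_THRESHOLD,
) -> DriverReport:
    """Pair one member's secretion with another's uptake of a pool metabolite.

    For every pool metabolite transported by at least two members, member
    i's transport flux is rank-correlated with the negated transport flux
    of member j; a pair with rho above ``threshold`` where i predominantly
    secretes (flux > 0) and j predominantly takes up (flux < 0) is
    reported as an exchanged (cross-fed) metabolite.
    """
    if len(fsm) < 3:
        raise ValueError("need at least three distinct samples")
    report = DriverReport()
    by_met: dict[str, list[tuple[str, str]]] = {}
    for rid, member_id, mid in _transport_table(eco):
        by_met.setdefault(mid, []).append((rid, member_id))
    for mid, carriers in by_met.items():
        if len(carriers) < 2:
            continue
        for rid_i, mem_i in carriers:
            for rid_j, mem_j in carriers:
                if mem_i == mem_j:
                    continue
                fi = fsm.samples[rid_i].to_numpy()
                fj = fsm.samples[rid_j].to_numpy()
                if np.ptp(fi) < 1e-12 or np.ptp(fj) < 1e-12:
                    report.skipped.append(f"{mid}:{mem_i}->{mem_j}")
                    continue
                if fi.mean() <= 0 or fj.mean() >= 0:
                    continue  # need i secreting and j taking up on average
                rho = float(spearmanr(fi, -fj).statistic)
                if rho > threshold:
                    report.exchanged.append((mid, mem_i, mem_j, rho))
    return report


def find_obligatory(
    eco: EcosystemModel,
    point,
    reactions=None,
    eps: float = 1e-6,
) -> set[str]:
    """Reactions whose FVA interval excludes zero at a pinned front point."""
    point = np.asarray(point, dtype=float)
    if point.shape != (eco.k,):
        raise ValueError(f"point must have {eco.k} coordinates")
    pins = {i: float(v) for i, v in enumerate(point)}
    fva = solve_fva(eco, reactions, objective_pins=pins)
    return {rid for rid, (lo, hi) in fva.items() if lo > eps or hi < -eps}
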