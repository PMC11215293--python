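"""Diagonal assembly of member models into a pool-compartment ecosystem.

Each member keeps its own stoichiometric block; its exchange reactions are
rewired into transport reactions (TR) between the organism's external
compartment and a shared pool compartment, and every metabolite reaching
the pool gets exactly one pool exchange reaction (ER) connecting the pool
to the environment.  Diet/media constraints act only on the ER bounds; TR
stay unconstrained (up to the numerical flux cap) so metabolites transit
freely between organisms and the pool.

Pool metabolite identity is the exchange metabolite id itself, so two
members sharing an id share the metabolite — namespace mapping (see
:mod:`ecoscore.model_io`) is the user's contract for making ids agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .model_io import DEFAULT_BOUND, MetabolicModel, detect_exchanges

__all__ = [
    "DietSpec",
    "EcosystemModel",
    "EcosystemBuildError",
    "build_ecosystem",
    "apply_diet",
    "remove_member",
    "read_diet",
    "write_diet",
]

#: members beyond this raise a soft warning (front enumeration cost grows fast)
MEMBER_SOFT_CAP = 11


class EcosystemBuildError(ValueError):
    pass


@dataclass
class DietSpec:
    """Bounds imposed on pool exchange reactions (and host blood reactions).

    ``lumen_bounds`` maps pool metabolite ids to (lower, upper) ER flux
    bounds; negative lower bounds supply the metabolite.  ER for
    metabolites not listed follow ``default_policy``: ``"unconstrained"``
    leaves them at the numerical cap (the permissive convention — blocking
    everything not in the diet starves the organisms of by-product routes),
    ``"blocked"`` forbids uptake (lower bound 0) while still allowing
    secretion.
    """

    name: str = "unconstrained"
    lumen_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    blood_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_policy: str = "unconstrained"

    def __post_init__(self) -> None:
        if self.default_policy not in ("unconstrained", "blocked"):
            raise ValueError(f"invalid default_policy {self.default_policy!r}")
        for table in (self.lumen_bounds, self.blood_bounds):
            for key, (lo, up) in table.items():
                if lo > up:
                    raise ValueError(f"diet {self.name!r}: lower > upper for {key!r}")


class EcosystemModel:
    """k member models joined through a pool compartment.

    Attributes
    ----------
    members : list of MetabolicModel
        The source models, in objective order.
    S : scipy.sparse.csr_matrix
        The ecosystem stoichiometric matrix (metabolite rows × reaction
        columns: every member block, TR, and ER).
    lb, ub : numpy arrays
        Flux bounds per reaction column.
    transport_reactions : dict (member_id, original exchange id) -> column id
    pool_exchanges : dict pool metabolite id -> column id
    """

    def __init__(self, members, reaction_ids, metabolite_ids, S, lb, ub,
                 objective_rows, member_columns, transport_reactions,
                 pool_exchanges, blood_reactions, flux_cap, diet=None):
        self.members: list[MetabolicModel] = members
        self.reaction_ids: list[str] = reaction_ids
        self.metabolite_ids: list[str] = metabolite_ids
        self.S: sparse.csr_matrix = S
        self.lb: np.ndarray = lb
        self.ub: np.ndarray = ub
        #: dense (k, n_bar) objective matrix; row i is member i's c vector
        self.C: np.ndarray = objective_rows
        self.member_columns: dict[str, list[int]] = member_columns
        self.transport_reactions: dict[tuple[str, str], str] = transport_reactions
        self.pool_exchanges: dict[str, str] = pool_exchanges
        self.blood_reactions: dict[str, list[str]] = blood_reactions
        self.flux_cap: float = flux_cap
        self.diet: DietSpec | None = diet
        self.diet_skipped: list[str] = []
        self._index = {rid: j for j, rid in enumerate(reaction_ids)}

    # -- basic introspection -------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.model_id for m in self.members]

    @property
    def n_bar(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self._index[rid]

    def bounds_of(self, rid: str) -> tuple[float, float]:
        j = self._index[rid]
        return float(self.lb[j]), float(self.ub[j])

    def transport_columns(self) -> list[str]:
        return list(self.transport_reactions.values())

    def copy(self) -> "EcosystemModel":
        eco = EcosystemModel(
            members=list(self.members),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective_rows=self.C.copy(),
            member_columns={k: list(v) for k, v in self.member_columns.items()},
            transport_reactions=dict(self.transport_reactions),
            pool_exchanges=dict(self.pool_exchanges),
            blood_reactions={k: list(v) for k, v in self.blood_reactions.items()},
            flux_cap=self.flux_cap,
            diet=self.diet,
        )
        eco.diet_skipped = list(self.diet_skipped)
        return eco

    def __repr__(self) -> str:
        return (
            f"<EcosystemModel k={self.k} members={self.member_ids} "
            f"n_bar={self.n_bar} ER={len(self.pool_exchanges)} "
            f"diet={self.diet.name if self.diet else None}>"
        )


def build_ecosystem(
    members: list[MetabolicModel],
    exchange_policy: str = "boundary",
    flux_cap: float = DEFAULT_BOUND,
) -> EcosystemModel:
    """Diagonally assemble ``members`` into one pool-compartment ecosystem.

    Exchange reactions of every member become TR into the pool; the union
    of exchanged metabolites across members defines the ER set.  TR and ER
    are unconstrained (±``flux_cap``) until a diet is applied.
    """
    if not members:
        raise EcosystemBuildError("need at least one member model")
    ids = [m.model_id for m in members]
    if len(set(ids)) != len(ids):
        raise EcosystemBuildError(f"duplicate member ids in {ids}")
    if len(members) > MEMBER_SOFT_CAP:
        warnings.warn(
            f"{len(members)} members exceeds the soft cap of {MEMBER_SOFT_CAP}; "
            "front enumeration may be slow",
            stacklevel=2,
        )

    reaction_ids: list[str] = []
    metabolite_rows: dict[str, int] = {}
    metabolite_ids: list[str] = []
    entries: list[tuple[int, int, float]] = []  # row, col, coef
    lb_list: list[float] = []
    ub_list: list[float] = []
    member_columns: dict[str, list[int]] = {}
    transport: dict[tuple[str, str], str] = {}
    pool_mets: list[str] = []
    blood_reactions: dict[str, list[str]] = {}
    objective_entries: list[tuple[int, int, float]] = []  # member idx, col, weight

    def row_of(met_key: str) -> int:
        if met_key not in metabolite_rows:
            metabolite_rows[met_key] = len(metabolite_ids)
            metabolite_ids.append(met_key)
        return metabolite_rows[met_key]

    for mi, member in enumerate(members):
        member.validate()
        exchanges = detect_exchanges(member, policy=exchange_policy)
        if not exchanges:
            warnings.warn(
                f"member {member.model_id!r} has no exchange reactions; "
                "it cannot interact through the pool",
                stacklevel=2,
            )
        blood = member.boundary_reactions(member.blood_compartments) if member.blood_compartments else set()
        cols = []
        for rxn in member.reactions.values():
            col = len(reaction_ids)
            rid = f"{member.model_id}:{rxn.id}"
            reaction_ids.append(rid)
            cols.append(col)
            if rxn.id in exchanges:
                # exchange -> transport reaction organism <-> pool
                (mid,) = rxn.stoichiometry
                coef = rxn.stoichiometry[mid]
                entries.append((row_of(f"{member.model_id}:{mid}"), col, coef))
                pool_key = f"pool:{mid}"
                if mid not in pool_mets:
                    pool_mets.append(mid)
                entries.append((row_of(pool_key), col, -coef))
                transport[(member.model_id, rxn.id)] = rid
                lb_list.append(-flux_cap)
                ub_list.append(flux_cap)
            else:
                for mid, coef in rxn.stoichiometry.items():
                    entries.append((row_of(f"{member.model_id}:{mid}"), col, coef))
                lb_list.append(rxn.lower_bound)
                ub_list.append(rxn.upper_bound)
            if rxn.id in blood:
                blood_reactions.setdefault(member.model_id, []).append(rid)
            w = member.objective.get(rxn.id, 0.0)
            if w != 0.0:
                objective_entries.append((mi, col, w))
        member_columns[member.model_id] = cols

    pool_exchanges: dict[str, str] = {}
    for mid in pool_mets:
        col = len(reaction_ids)
        rid = f"ER_{mid}"
        reaction_ids.append(rid)
        entries.append((metabolite_rows[f"pool:{mid}"], col, -1.0))
        lb_list.append(-flux_cap)
        ub_list.append(flux_cap)
        pool_exchanges[mid] = rid

    n = len(reaction_ids)
    rows, cols_, data = zip(*entries)
    S = sparse.csr_matrix(
        (data, (rows, cols_)), shape=(len(metabolite_ids), n)
    )
    C = np.zeros((len(members), n))
    for mi, col, w in objective_entries:
        C[mi, col] = w

    return EcosystemModel(
        members=list(members),
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        S=S,
        lb=np.array(lb_list),
        ub=np.array(ub_list),
        objective_rows=C,
        member_columns=member_columns,
        transport_reactions=transport,
        pool_exchanges=pool_exchanges,
        blood_reactions=blood_reactions,
        flux_cap=flux_cap,
    )


def apply_diet(eco: EcosystemModel, diet: DietSpec) -> EcosystemModel:
    """Return a new ecosystem with ER (and host blood) bounds set from ``diet``.

    Diet entries that match neither an ER metabolite nor a member blood
    reaction are collected in ``diet_skipped`` (reported, not fatal).
    """
    out = eco.copy()
    skipped: list[str] = []
    cap = out.flux_cap

    for mid, er_id in out.pool_exchanges.items():
        j = out.reaction_index(er_id)
        if mid in diet.lumen_bounds:
            lo, up = diet.lumen_bounds[mid]
            out.lb[j], out.ub[j] = lo, up
        elif diet.default_policy == "blocked":
            out.lb[j], out.ub[j] = 0.0, cap  # no uptake; secretion allowed
        else:
            out.lb[j], out.ub[j] = -cap, cap
    for mid in diet.lumen_bounds:
        if mid not in out.pool_exchanges:
            skipped.append(f"lumen:{mid}")

    blood_cols = {rid for rids in out.blood_reactions.values() for rid in rids}
    for rid, (lo, up) in diet.blood_bounds.items():
        hits = [
            full
            for full in blood_cols
            if full.split(":", 1)[1] == rid
        ]
        if not hits:
            skipped.append(f"blood:{rid}")
            continue
        for full in hits:
            j = out.reaction_index(full)
            out.lb[j], out.ub[j] = lo, up

    if skipped:
        warnings.warn(f"diet {diet.name!r}: unresolved ids skipped: {skipped}", stacklevel=2)
    out.diet = diet
    out.diet_skipped = skipped
    return out


def remove_member(eco: EcosystemModel, member_id: str) -> EcosystemModel:
    """Rebuild the ecosystem without ``member_id`` and re-apply its diet."""
    ids = eco.member_ids
    if member_id not in ids:
        raise KeyError(f"no member {member_id!r} in {ids}")
    remaining = [m for m in eco.members if m.model_id != member_id]
    if len(remaining) < 2:
        raise EcosystemBuildError(
            "removing a member must leave at least two (no interaction to score otherwise)"
        )
    out = build_ecosystem(remaining, flux_cap=eco.flux_cap)
    if eco.diet is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = apply_diet(out, eco.diet)
    return out


# ---------------------------------------------------------------------------
# diet file I/O: TSV (metabolite_id, lower, upper) or YAML with inline tables


def read_diet(path: str | Path) -> DietSpec:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        lumen = {str(k): (float(v[0]), float(v[1])) for k, v in (doc.get("lumen") or {}).items()}
        blood = {str(k): (float(v[0]), float(v[1])) for k, v in (doc.get("blood") or {}).items()}
        for key, attr in (("lumen_table", lumen), ("blood_table", blood)):
            sub = doc.get(key)
            if sub:
                attr.update(_read_bounds_tsv(path.parent / sub))
        return DietSpec(
            name=doc.get("name", path.stem),
            lumen_bounds=lumen,
            blood_bounds=blood,
            default_policy=doc.get("default_policy", "unconstrained"),
        )
    return DietSpec(name=path.stem, lumen_bounds=_read_bounds_tsv(path))


def _read_bounds_tsv(path: Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:3])
    return {
        str(row[cols[0]]): (float(row[cols[1]]), float(row[cols[2]]))
        for _, row in df.iterrows()
    }


def write_diet(diet: DietSpec, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = {
            "name": diet.name,
            "default_policy": diet.default_policy,
            "lumen": {k: list(v) for k, v in diet.lumen_bounds.items()},
            "blood": {k: list(v) for k, v in diet.blood_bounds.items()},
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        rows = [(m, lo, up) for m, (lo, up) in diet.lumen_bounds.items()]
        pd.DataFrame(rows, columns=["metabolite_id", "lower", "upper"]).to_csv(
            path, sep="\t", index=False
        )
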