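"""Small metabolic models with known ground-truth interaction structure.

Every other module is testable against these toys without downloading any
genome-scale model.  Four pairwise motifs are generated:

* ``competition`` — both members consume one pooled substrate (S < 0);
* ``neutralism`` — disjoint substrates (S = 0);
* ``crossfeed_oneway`` — member A obligatorily secretes a by-product that
  boosts member B beyond its alone optimum (FavorsBacteria);
* ``crossfeed_mutual`` — reciprocal obligate by-product exchange with both
  alone-growths substrate-limited (Mutualism, S > 0).

Obligate secretion is encoded by coupling the by-product directly into
the biomass reaction's stoichiometry, which guarantees the correlation
structure the front-sampling analyses look for.  All stoichiometries and
bounds are integer-friendly so oracle arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ecosystem import DietSpec
from .model_io import DEFAULT_BOUND, MetabolicModel, Reaction

__all__ = [
    "ToySpec",
    "generate_pair",
    "generate_host_like",
    "generate_host_pair",
    "generate_community",
]

KINDS = ("competition", "neutralism", "crossfeed_oneway", "crossfeed_mutual")

#: per-kind default substrate bounds (mmol·gDW⁻¹·h⁻¹ supplied by the diet)
_DEFAULT_BOUNDS = {
    "competition": (10.0, 10.0),
    "neutralism": (5.0, 7.0),
    "crossfeed_oneway": (10.0, 1.0),
    "crossfeed_mutual": (1.0, 1.0),
}


@dataclass(frozen=True)
class ToySpec:
    kind: str = "competition"
    n_members: int = 2
    yields: tuple[float, ...] = (1.0, 1.0)
    substrate_bound: float | tuple[float, ...] | None = None
    byproduct_stoich: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown toy kind {self.kind!r}; choose from {KINDS}")
        if any(y <= 0 for y in self.yields):
            raise ValueError("yields must be positive")
        if self.byproduct_stoich < 0:
            raise ValueError("byproduct_stoich must be nonnegative")

    def bounds(self) -> tuple[float, ...]:
        b = self.substrate_bound
        if b is None:
            b = _DEFAULT_BOUNDS[self.kind]
        if np.isscalar(b):
            b = (float(b),) * max(self.n_members, 2)
        return tuple(float(x) for x in b)

    @classmethod
    def random(cls, kind: str, seed: int, n_members: int = 2) -> "ToySpec":
        """Randomized but integer-friendly parameterization (seed-fixed)."""
        rng = np.random.default_rng(seed)
        yields = tuple(rng.choice([0.5, 1.0, 2.0]) for _ in range(n_members))
        bounds = tuple(float(rng.integers(3, 13)) for _ in range(n_members))
        coupling = float(rng.choice([0.25, 0.5, 1.0]))
        return cls(
            kind=kind,
            n_members=n_members,
            yields=yields,
            substrate_bound=bounds,
            byproduct_stoich=coupling,
            seed=seed,
        )


def _chain_member(model_id, substrate, y, extra_products=None, extra_substrates=None):
    """EX -> transport -> biomass chain member on one external substrate.

    ``extra_products``: {external_met: stoich} coupled into the biomass
    reaction (obligate secretion, with its own exchange).
    ``extra_substrates``: external metabolites convertible into the same
    internal fuel (alternative nutrient routes, with their own exchange).
    """
    extra_products = extra_products or {}
    extra_substrates = extra_substrates or []
    mets = {substrate: "e", "fuel_c": "c"}
    rxns: dict[str, Reaction] = {}
    rxns[f"EX_{substrate}"] = Reaction(f"EX_{substrate}", {substrate: -1.0})
    rxns[f"T_{substrate}"] = Reaction(
        f"T_{substrate}", {substrate: -1.0, "fuel_c": 1.0}, 0.0, DEFAULT_BOUND
    )
    for ext in extra_substrates:
        mets[ext] = "e"
        rxns[f"EX_{ext}"] = Reaction(f"EX_{ext}", {ext: -1.0})
        rxns[f"T_{ext}"] = Reaction(f"T_{ext}", {ext: -1.0, "fuel_c": 1.0}, 0.0, DEFAULT_BOUND)
    bio = {"fuel_c": -1.0 / y}
    for ext, coef in extra_products.items():
        mets[ext] = "e"
        bio[ext] = coef
        rxns[f"EX_{ext}"] = Reaction(f"EX_{ext}", {ext: -1.0})
    rxns["BIOMASS"] = Reaction("BIOMASS", bio, 0.0, DEFAULT_BOUND)
    return MetabolicModel(
        model_id=model_id,
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        external_compartments={"e"},
    ).validate()


def generate_pair(spec: ToySpec) -> tuple[list[MetabolicModel], DietSpec]:
    """Two-member toy ecosystem with the ground truth fixed by ``spec.kind``."""
    if spec.n_members != 2:
        raise ValueError("generate_pair requires n_members = 2")
    yA, yB = spec.yields[:2]
    bA, bB = spec.bounds()[:2]
    c = spec.byproduct_stoich
    cap = DEFAULT_BOUND

    if spec.kind == "competition":
        A = _chain_member("org_a", "s_e", yA)
        B = _chain_member("org_b", "s_e", yB)
        diet = DietSpec(name="competition", lumen_bounds={"s_e": (-bA, cap)})
    elif spec.kind == "neutralism":
        A = _chain_member("org_a", "s1_e", yA)
        B = _chain_member("org_b", "s2_e", yB)
        diet = DietSpec(
            name="neutralism",
            lumen_bounds={"s1_e": (-bA, cap), "s2_e": (-bB, cap)},
        )
    elif spec.kind == "crossfeed_oneway":
        A = _chain_member("org_a", "s1_e", yA, extra_products={"p_e": c})
        B = _chain_member("org_b", "s2_e", yB, extra_substrates=["p_e"])
        diet = DietSpec(
            name="crossfeed_oneway",
            lumen_bounds={
                "s1_e": (-bA, cap),
                "s2_e": (-bB, cap),
                "p_e": (0.0, cap),  # by-product only available via secretion
            },
        )
    else:  # crossfeed_mutual
        A = _chain_member(
            "org_a", "s1_e", yA, extra_products={"pa_e": c}, extra_substrates=["pb_e"]
        )
        B = _chain_member(
            "org_b", "s2_e", yB, extra_products={"pb_e": c}, extra_substrates=["pa_e"]
        )
        diet = DietSpec(
            name="crossfeed_mutual",
            lumen_bounds={
                "s1_e": (-bA, cap),
                "s2_e": (-bB, cap),
                "pa_e": (0.0, cap),
                "pb_e": (0.0, cap),
            },
        )
    return [A, B], diet


def expected_sign(kind: str) -> str:
    return {"competition": "-", "neutralism": "0"}.get(kind, "+")


def expected_type(kind: str) -> str:
    return {
        "competition": "Competition",
        "neutralism": "Neutralism",
        "crossfeed_oneway": "FavorsBacteria",
        "crossfeed_mutual": "Mutualism",
    }[kind]


def generate_host_like(
    model_id: str = "host",
    fuel_bound_met: str = "glc_l",
    cofactor_met: str = "chol_l",
    cofactor_demand: float = 0.5,
    waste_yield: float = 0.2,
) -> MetabolicModel:
    """Host-style member: lumen exchanges, blood sinks, maintenance objective.

    The objective models cellular maintenance (membrane, protein, energy
    turnover) rather than replication; structurally it is a flux like any
    biomass objective.  Blood-compartment boundary reactions move waste
    out of the cell and are never exchange reactions: only the lumen side
    talks to the pool.
    """
    mets = {
        fuel_bound_met: "l",
        cofactor_met: "l",
        "fuel_c": "c",
        "cof_c": "c",
        "waste_c": "c",
        "waste_b": "b",
    }
    rxns = {
        f"EX_{fuel_bound_met}": Reaction(f"EX_{fuel_bound_met}", {fuel_bound_met: -1.0}),
        f"T_{fuel_bound_met}": Reaction(
            f"T_{fuel_bound_met}", {fuel_bound_met: -1.0, "fuel_c": 1.0}, 0.0, DEFAULT_BOUND
        ),
        f"EX_{cofactor_met}": Reaction(f"EX_{cofactor_met}", {cofactor_met: -1.0}),
        f"T_{cofactor_met}": Reaction(
            f"T_{cofactor_met}", {cofactor_met: -1.0, "cof_c": 1.0}, 0.0, DEFAULT_BOUND
        ),
        "MAINTENANCE": Reaction(
            "MAINTENANCE",
            {"fuel_c": -1.0, "cof_c": -cofactor_demand, "waste_c": waste_yield},
            0.0,
            DEFAULT_BOUND,
        ),
        "T_waste_blood": Reaction(
            "T_waste_blood", {"waste_c": -1.0, "waste_b": 1.0}, 0.0, DEFAULT_BOUND
        ),
        "SINK_waste_b": Reaction("SINK_waste_b", {"waste_b": -1.0}, 0.0, DEFAULT_BOUND),
    }
    return MetabolicModel(
        model_id=model_id,
        metabolites=mets,
        reactions=rxns,
        objective={"MAINTENANCE": 1.0},
        external_compartments={"l", "b"},
        blood_compartments={"b"},
    ).validate()


def generate_host_pair(
    cofactor_secretion: float = 1.0,
) -> tuple[list[MetabolicModel], DietSpec]:
    """Host plus a bacterium secreting the host's limiting cofactor.

    The construction makes the host cofactor-limited alone, so bacterial
    secretion raises host maintenance (FavorsHost) while the bacterium is
    unaffected.
    """
    host = generate_host_like()
    bug = _chain_member("bug", "s2_e", 1.0, extra_products={"chol_l": cofactor_secretion})
    cap = DEFAULT_BOUND
    diet = DietSpec(
        name="host_pair",
        lumen_bounds={
            "glc_l": (-10.0, cap),
            "chol_l": (-1.0, cap),
            "s2_e": (-1.0, cap),
        },
        blood_bounds={"SINK_waste_b": (0.0, cap)},
    )
    return [host, bug], diet


def generate_community(spec: ToySpec) -> tuple[list[MetabolicModel], DietSpec, pd.DataFrame]:
    """Community of 3–11 members: one interacting motif pair + neutral rest.

    Members 0 and 1 carry the motif selected by ``spec.kind``
    (cross-feeding, competition, or nothing for ``neutralism``); all
    remaining members grow on private substrates.  The returned DataFrame
    is the machine-readable ground truth of expected pairwise interaction
    signs ('+', '-', '0').
    """
    n = spec.n_members
    if not 3 <= n <= 11:
        raise ValueError("community size must be between 3 and 11 members")
    rng = np.random.default_rng(spec.seed)
    cap = DEFAULT_BOUND

    pair_spec = replace(spec, n_members=2)
    if spec.kind == "neutralism":
        members: list[MetabolicModel] = []
        lumen: dict[str, tuple[float, float]] = {}
    else:
        members, pair_diet = generate_pair(pair_spec)
        members = [replace_id(members[0], "org_0"), replace_id(members[1], "org_1")]
        lumen = dict(pair_diet.lumen_bounds)

    start = len(members)
    for i in range(start, n):
        bound = float(rng.integers(3, 9))
        sub = f"n{i}_e"
        members.append(_chain_member(f"org_{i}", sub, 1.0))
        lumen[sub] = (-bound, cap)

    sign = np.full((n, n), "0", dtype=object)
    np.fill_diagonal(sign, "")
    if spec.kind != "neutralism":
        s = expected_sign(spec.kind)
        sign[0, 1] = sign[1, 0] = s
    ids = [m.model_id for m in members]
    truth = pd.DataFrame(sign, index=ids, columns=ids)
    diet = DietSpec(name=f"community_{spec.kind}", lumen_bounds=lumen)
    return members, diet, truth


def replace_id(model: MetabolicModel, new_id: str) -> MetabolicModel:
    out = model.copy()
    out.model_id = new_id
    return out
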