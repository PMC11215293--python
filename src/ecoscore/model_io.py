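"""Single-organism metabolic model container and I/O.

A :class:`MetabolicModel` is a plain stoichiometric description of one
organism: metabolites with compartments, reactions with flux bounds in
mmol·gDW⁻¹·h⁻¹, and a linear objective (the ``c`` vector, typically a
biomass or maintenance reaction).  SBML Level 3 + FBC files are read and
written through cobrapy; a two-table TSV dialect (``reactions.tsv`` +
``metabolites.tsv``) is provided so that small fixtures need no XML.

Flux sign convention (BiGG): for an exchange/boundary reaction written as
``m ->``, negative flux is uptake into the organism and positive flux is
secretion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Reaction",
    "MetabolicModel",
    "NamespaceMap",
    "ModelFormatError",
    "ModelValidationError",
    "read_model",
    "write_model",
    "detect_exchanges",
    "apply_namespace",
]

#: flux bound used when a file leaves a bound unspecified (community convention)
DEFAULT_BOUND = 1000.0

#: compartment tag of host blood metabolites; blood boundary reactions are
#: never treated as exchanges (they stay private to the host model)
DEFAULT_BLOOD_TAG = "b"


class ModelFormatError(ValueError):
    """A file did not parse under the named standard."""


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound, self.upper_bound)


@dataclass
class MetabolicModel:
    """One organism's stoichiometry, flux bounds, and objective."""

    model_id: str
    metabolites: dict[str, str]  # metabolite_id -> compartment_id
    reactions: dict[str, Reaction]  # insertion-ordered
    objective: dict[str, float]  # reaction_id -> weight (the c vector)
    external_compartments: set[str] = field(default_factory=set)
    blood_compartments: set[str] = field(default_factory=set)

    def validate(self) -> "MetabolicModel":
        if not self.objective:
            raise ModelValidationError(f"model {self.model_id!r}: empty objective")
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelValidationError(
                    f"model {self.model_id!r}: objective references unknown reaction {rid!r}"
                )
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"model {self.model_id!r}: reaction {rxn.id!r} has lower_bound > upper_bound"
                )
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"model {self.model_id!r}: reaction {rxn.id!r} references "
                        f"undeclared metabolite {mid!r}"
                    )
        return self

    @property
    def exchange_ids(self) -> set[str]:
        """Exchange reactions under the boundary policy (lumen side only)."""
        return detect_exchanges(self, policy="boundary")

    def boundary_reactions(self, compartments: set[str] | None = None) -> set[str]:
        """Single-metabolite reactions touching the given compartments."""
        out = set()
        for rxn in self.reactions.values():
            if len(rxn.stoichiometry) != 1:
                continue
            (mid,) = rxn.stoichiometry
            comp = self.metabolites[mid]
            if compartments is None or comp in compartments:
                out.add(rxn.id)
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective=dict(self.objective),
            external_compartments=set(self.external_compartments),
            blood_compartments=set(self.blood_compartments),
        )


@dataclass
class NamespaceMap:
    """Injective id-renaming table used to reconcile model nomenclatures."""

    entries: dict[str, str]
    scope: str = "metabolite"  # "metabolite" | "reaction"

    def __post_init__(self) -> None:
        if self.scope not in ("metabolite", "reaction"):
            raise ValueError(f"invalid namespace scope {self.scope!r}")
        targets = [t for s, t in self.entries.items() if s != t]
        if len(targets) != len(set(targets)):
            raise ModelValidationError("namespace map is not injective")

    def get(self, key: str) -> str:
        return self.entries.get(key, key)

    @classmethod
    def from_tsv(cls, path: str | Path, scope: str = "metabolite") -> "NamespaceMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ModelFormatError(f"{path}: namespace map needs two columns")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])), scope=scope)


# ---------------------------------------------------------------------------
# equation-string dialect


def parse_equation(eq: str) -> dict[str, float]:
    """Parse ``"2 a_c + b_c -> c_c"`` into a stoichiometry map.

    The arrow (``->`` or ``<=>``) is informational; reversibility is set by
    the bounds columns.  Either side may be empty (boundary reactions).
    """
    m = re.split(r"->|<=>|<->", eq)
    if len(m) != 2:
        raise ModelFormatError(f"equation {eq!r}: expected one '->' or '<=>'")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"equation {eq!r}: empty term")
            parts = term.split()
            if len(parts) == 1:
                coef, mid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelFormatError(f"equation {eq!r}: bad coefficient {parts[0]!r}") from exc
                mid = parts[1]
            else:
                raise ModelFormatError(f"equation {eq!r}: bad term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(m[0], -1.0)
    add_side(m[1], +1.0)
    return {k: v for k, v in stoich.items() if v != 0.0}


def format_equation(stoich: dict[str, float]) -> str:
    def fmt(coef: float, mid: str) -> str:
        return mid if coef == 1.0 else f"{coef:g} {mid}"

    lhs = " + ".join(fmt(-c, m) for m, c in stoich.items() if c < 0)
    rhs = " + ".join(fmt(c, m) for m, c in stoich.items() if c > 0)
    return f"{lhs} -> {rhs}"


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tabular"
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    raise ModelFormatError(f"cannot infer model format from {path}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read an SBML (L3+FBC) or tabular model from ``path``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "tabular":
        return _read_tabular(path)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular")
    if fmt == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    elif fmt == "tabular":
        _write_tabular(model, path)
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


def _read_tabular(path: Path) -> MetabolicModel:
    rxn_path = path / "reactions.tsv"
    met_path = path / "metabolites.tsv"
    for p in (rxn_path, met_path):
        if not p.exists():
            raise ModelFormatError(f"tabular model directory {path} is missing {p.name}")
    mets = pd.read_csv(met_path, sep="\t", dtype={"id": str, "compartment": str})
    rxns = pd.read_csv(rxn_path, sep="\t", dtype={"id": str, "equation": str})
    for col in ("id", "compartment"):
        if col not in mets.columns:
            raise ModelFormatError(f"{met_path}: missing column {col!r}")
    for col in ("id", "equation"):
        if col not in rxns.columns:
            raise ModelFormatError(f"{rxn_path}: missing column {col!r}")

    metabolites = dict(zip(mets["id"], mets["compartment"]))
    external = set()
    blood = set()
    if "external" in mets.columns:
        external = set(mets.loc[mets["external"].astype(bool), "compartment"])
    if "blood" in mets.columns:
        blood = set(mets.loc[mets["blood"].astype(bool), "compartment"])

    reactions: dict[str, Reaction] = {}
    objective: dict[str, float] = {}
    for _, row in rxns.iterrows():
        lb = float(row["lb"]) if "lb" in rxns.columns and pd.notna(row.get("lb")) else -DEFAULT_BOUND
        ub = float(row["ub"]) if "ub" in rxns.columns and pd.notna(row.get("ub")) else DEFAULT_BOUND
        rid = row["id"]
        reactions[rid] = Reaction(rid, parse_equation(row["equation"]), lb, ub)
        w = row.get("objective", 0.0) if "objective" in rxns.columns else 0.0
        if pd.notna(w) and float(w) != 0.0:
            objective[rid] = float(w)

    return MetabolicModel(
        model_id=path.name,
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        external_compartments=external,
        blood_compartments=blood,
    ).validate()


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        {
            "id": list(model.metabolites),
            "compartment": [model.metabolites[m] for m in model.metabolites],
        }
    )
    mets["external"] = [int(c in model.external_compartments) for c in mets["compartment"]]
    mets["blood"] = [int(c in model.blood_compartments) for c in mets["compartment"]]
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions.values()],
            "equation": [format_equation(r.stoichiometry) for r in model.reactions.values()],
            "lb": [r.lower_bound for r in model.reactions.values()],
            "ub": [r.upper_bound for r in model.reactions.values()],
            "objective": [model.objective.get(r.id, 0.0) for r in model.reactions.values()],
        }
    )
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of exception types
        raise ModelFormatError(f"failed to parse SBML file {path}: {exc}") from exc
    model = from_cobra(cm)
    if not model.model_id:
        model.model_id = path.stem
    return model.validate()


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model (objective coefficients, bounds, compartments)."""
    from cobra.util.solver import linear_reaction_coefficients

    metabolites = {m.id: (m.compartment or "") for m in cm.metabolites}
    reactions = {
        r.id: Reaction(
            r.id,
            {m.id: float(c) for m, c in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
        )
        for r in cm.reactions
    }
    objective = {r.id: float(c) for r, c in linear_reaction_coefficients(cm).items() if c != 0}
    # external compartments: prefer those of EX_-prefixed boundary reactions
    # (BiGG convention); fall back to all boundary compartments
    external = set()
    fallback = set()
    for r in cm.reactions:
        if len(r.metabolites) == 1:
            (m,) = r.metabolites
            if not m.compartment:
                continue
            fallback.add(m.compartment)
            if r.id.startswith("EX_"):
                external.add(m.compartment)
    external = external or fallback
    return MetabolicModel(
        model_id=cm.id or "",
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        external_compartments=external,
    )


def to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {
        mid: cobra.Metabolite(mid, compartment=comp or None)
        for mid, comp in model.metabolites.items()
    }
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    cm.objective = {
        cm.reactions.get_by_id(rid): w for rid, w in model.objective.items()
    }
    return cm


# ---------------------------------------------------------------------------
# exchange detection and namespace application


def detect_exchanges(
    model: MetabolicModel,
    policy: str = "boundary",
    prefix: str = "EX_",
    blood_tag: str | None = None,
) -> set[str]:
    """Identify a model's exchange reactions.

    ``prefix`` policy flags reaction ids beginning with ``prefix``;
    ``boundary`` policy flags single-metabolite reactions whose metabolite
    sits in an external compartment.  Under both policies, boundary
    reactions on blood compartments (host model) are excluded: they move
    metabolites between the host and its bloodstream, not the shared
    environment.
    """
    blood = set(model.blood_compartments)
    if blood_tag is not None:
        blood.add(blood_tag)
    elif not blood:
        blood = {DEFAULT_BLOOD_TAG} & set(model.metabolites.values())

    def in_blood(rid: str) -> bool:
        st = model.reactions[rid].stoichiometry
        if len(st) != 1:
            return False
        (mid,) = st
        return model.metabolites[mid] in blood

    if policy == "prefix":
        return {
            rid for rid in model.reactions if rid.startswith(prefix) and not in_blood(rid)
        }
    if policy == "boundary":
        out = set()
        for rxn in model.reactions.values():
            if len(rxn.stoichiometry) != 1:
                continue
            (mid,) = rxn.stoichiometry
            comp = model.metabolites[mid]
            if comp in blood:
                continue
            # with no declared external compartments, any non-blood boundary
            # reaction counts as an exchange
            if model.external_compartments and comp not in model.external_compartments:
                continue
            out.add(rxn.id)
        return out
    raise ValueError(f"unknown exchange policy {policy!r}")


def apply_namespace(model: MetabolicModel, nsmap: NamespaceMap) -> MetabolicModel:
    """Rename metabolite or reaction ids; unmapped ids pass through."""
    out = model.copy()
    if nsmap.scope == "metabolite":
        renamed = {}
        for mid, comp in out.metabolites.items():
            new = nsmap.get(mid)
            if new in renamed:
                raise ModelValidationError(
                    f"namespace map collides metabolites {mid!r} and existing {new!r}"
                )
            renamed[new] = comp
        if len(renamed) != len(out.metabolites):
            raise ModelValidationError("namespace map collides two distinct metabolite ids")
        out.metabolites = renamed
        for rxn in out.reactions.values():
            rxn.stoichiometry = {nsmap.get(m): c for m, c in rxn.stoichiometry.items()}
    else:
        renamed_r: dict[str, Reaction] = {}
        for rid, rxn in out.reactions.items():
            new = nsmap.get(rid)
            if new in renamed_r:
                raise ModelValidationError(
                    f"namespace map collides reactions {rid!r} and existing {new!r}"
                )
            rxn.id = new
            renamed_r[new] = rxn
        if len(renamed_r) != len(out.reactions):
            raise ModelValidationError("namespace map collides two distinct reaction ids")
        out.reactions = renamed_r
        out.objective = {nsmap.get(r): w for r, w in out.objective.items()}
    return out.validate()
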