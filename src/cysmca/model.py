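"""Reduced stoichiometric model of E. coli central carbon and L-cysteine metabolism.

The packaged model covers glycolysis, the pentose phosphate pathway, the
citrate cycle and the L-cysteine biosynthesis/export route of an engineered
producer strain, condensed to 37 reactions.  Species are labelled with
BiGG-style short identifiers.  External species (extracellular glucose and
the exported products) and clamped currency metabolites are excluded from
the balanced rows of the stoichiometric matrix used for control analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MetaboliteSpec",
    "ReactionSpec",
    "MetabolicModel",
    "ModelValidationError",
    "build_reduced_model",
    "stoichiometric_matrix",
    "augment_model",
    "carbon_map",
    "PSEUDO_REACTIONS",
]

#: Pseudo/transport reactions exempt from elemental carbon balancing:
#: the lumped respiratory NADH dehydrogenase, the lumped ATP synthase and
#: the coupled OAS/L-cysteine exporter (a transport step, no chemistry).
PSEUDO_REACTIONS = frozenset({"NADH5", "ATPS", "YdeD"})


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """A chemical species of the reduced model.

    ``internal`` species are balanced at steady state; external species
    (``internal=False``) are clamped boundary conditions — feed substrates,
    exported products, water and the currency/cofactor pools held constant
    during short-term perturbations.
    """

    id: str
    name: str = ""
    internal: bool = True
    carbon_atoms: int | None = None
    formula: str | None = None
    dG_f: float | None = None

    def __post_init__(self) -> None:
        if self.carbon_atoms is not None and self.carbon_atoms < 0:
            raise ModelValidationError(
                f"metabolite {self.id!r}: carbon_atoms must be >= 0"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction with signed stoichiometry (reactants < 0, products > 0)."""

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    dG0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )

    @property
    def reactants(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    """Ordered collections of metabolites and reactions."""

    metabolites: list[MetaboliteSpec]
    reactions: list[ReactionSpec]
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.internal]

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        try:
            return next(m for m in self.metabolites if m.id == met_id)
        except StopIteration:
            raise KeyError(f"no metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> ReactionSpec:
        try:
            return next(r for r in self.reactions if r.id == rxn_id)
        except StopIteration:
            raise KeyError(f"no reaction {rxn_id!r}") from None

    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )

    def with_internal_set(self, internal_ids: Iterable[str]) -> "MetabolicModel":
        """Return a copy with the balanced/internal designation replaced."""
        internal = set(internal_ids)
        unknown = internal - set(self.metabolite_ids)
        if unknown:
            raise ModelValidationError(f"unknown metabolites: {sorted(unknown)}")
        mets = [replace(m, internal=(m.id in internal)) for m in self.metabolites]
        return MetabolicModel(mets, list(self.reactions), name=self.name)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolites), list(self.reactions), name=self.name
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.name == other.name
        )


# ---------------------------------------------------------------------------
# construction & matrices
# ---------------------------------------------------------------------------

def build_reduced_model() -> MetabolicModel:
    """Load the packaged 37-reaction reduced model.

    The fixture collapses the duplicated acetyl-CoA synthetase row of the
    printed table into a single ACS reaction.  Default boundary designation:
    extracellular species, water and currency/cofactor pools are external;
    the 33 pathway intermediates are balanced.
    """
    ref = resources.files("cysmca.data").joinpath("reduced_model.json")
    with ref.open("r") as fh:
        payload = json.load(fh)
    return model_from_dict(payload)


def model_from_dict(payload: Mapping) -> MetabolicModel:
    mets = [
        MetaboliteSpec(
            id=m["id"],
            name=m.get("name", ""),
            internal=m.get("internal", True),
            carbon_atoms=m.get("carbon_atoms"),
            formula=m.get("formula"),
            dG_f=m.get("dG_f"),
        )
        for m in payload["metabolites"]
    ]
    rxns = [
        ReactionSpec(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry=r["stoichiometry"],
            reversible=r.get("reversible", False),
            lower_bound=r.get("lower_bound", 0.0),
            upper_bound=r.get("upper_bound", 1000.0),
            dG0=r.get("dG0"),
        )
        for r in payload["reactions"]
    ]
    return MetabolicModel(mets, rxns, name=payload.get("name", ""))


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "internal": m.internal,
                "carbon_atoms": m.carbon_atoms,
                "formula": m.formula,
                "dG_f": m.dG_f,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "reversible": r.reversible,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "dG0": r.dG0,
            }
            for r in model.reactions
        ],
    }


def stoichiometric_matrix(
    model: MetabolicModel, internal_only: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense stoichiometric matrix N (metabolites x reactions).

    Returns ``(N, row_ids, column_ids)``; entry ``(j, i)`` is the signed
    coefficient of metabolite ``j`` in reaction ``i``.  With
    ``internal_only`` the rows are restricted to balanced species.
    """
    if internal_only:
        rows = model.internal_metabolite_ids
    else:
        rows = model.metabolite_ids
    cols = model.reaction_ids
    index = {m: j for j, m in enumerate(rows)}
    N = np.zeros((len(rows), len(cols)))
    for i, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            j = index.get(met)
            if j is not None:
                N[j, i] = coef
    return N, rows, cols


def augment_model(
    model: MetabolicModel,
    extra_reactions: Sequence[ReactionSpec] = (),
    extra_metabolites: Sequence[MetaboliteSpec] = (),
) -> MetabolicModel:
    """Return a new model with additional reactions (and metabolites).

    The input model is left untouched.  Identifier collisions raise.
    """
    for met in extra_metabolites:
        if met.id in model.metabolite_ids:
            raise ModelValidationError(f"metabolite id already present: {met.id!r}")
    for rxn in extra_reactions:
        if rxn.id in model.reaction_ids:
            raise ModelValidationError(f"reaction id already present: {rxn.id!r}")
    return MetabolicModel(
        list(model.metabolites) + list(extra_metabolites),
        list(model.reactions) + list(extra_reactions),
        name=model.name,
    )


def carbon_map(
    model: MetabolicModel, metabolite_ids: Iterable[str] | None = None
) -> dict[str, int]:
    """Carbon atoms per metabolite, for carbon-balance bookkeeping.

    Cofactor carriers follow the transferred-moiety convention (CoA counts
    zero, acetyl-CoA counts the two acetyl carbons) so that chemistry rows
    balance without tracking the carrier skeletons.
    """
    wanted = list(metabolite_ids) if metabolite_ids is not None else model.metabolite_ids
    out: dict[str, int] = {}
    missing: list[str] = []
    for met_id in wanted:
        met = model.metabolite(met_id)
        if met.carbon_atoms is None:
            missing.append(met_id)
        else:
            out[met_id] = met.carbon_atoms
    if missing:
        raise ModelValidationError(
            f"metabolites without carbon annotation: {missing}"
        )
    return out


def carbon_imbalance(model: MetabolicModel, rxn_id: str) -> float:
    """Net carbon atoms produced by a reaction (0 for a balanced one)."""
    rxn = model.reaction(rxn_id)
    cmap = carbon_map(model, rxn.stoichiometry.keys())
    return float(sum(coef * cmap[m] for m, coef in rxn.stoichiometry.items()))
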