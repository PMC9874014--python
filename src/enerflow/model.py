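"""Lightweight constraint-based metabolic model container.

A :class:`MetabolicModel` holds exactly what flux balance analysis needs:
a stoichiometric matrix (as per-reaction metabolite coefficient maps),
flux bounds, boolean gene-reaction rule strings, and the id of the
objective (ATP demand) reaction.  The JSON serialisation follows the
cobrapy JSON schema, so models written here load unchanged in cobrapy
and vice versa for simple models.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = ["Reaction", "MetabolicModel", "read_json_model", "write_json_model"]


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  A reaction touching a single metabolite is treated as an
    exchange (boundary) pseudo-reaction, the usual COBRA convention.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0


@dataclass
class MetabolicModel:
    id: str
    reactions: list[Reaction]
    objective_id: str
    name: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if self.objective_id not in set(ids):
            raise ValueError(f"objective reaction {self.objective_id!r} not in model")

    # -- access helpers -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                seen.setdefault(met)
        return list(seen)

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for_metabolite(self, met_id: str) -> Reaction | None:
        for rxn in self.exchanges:
            if met_id in rxn.stoichiometry:
                return rxn
        return None

    def genes(self) -> set[str]:
        from .gpr import parse_gpr

        out: set[str] = set()
        for rxn in self.reactions:
            out |= parse_gpr(rxn.gene_rule).genes()
        return out

    def stoichiometric_matrix(self) -> tuple[sp.csr_matrix, list[str], list[str]]:
        """Return (S, metabolite ids, reaction ids); S is mets x reactions."""
        mets = self.metabolite_ids
        met_index = {m: i for i, m in enumerate(mets)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coef))
        shape = (len(mets), len(self.reactions))
        return sp.csr_matrix((data, (rows, cols)), shape=shape), mets, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_id=self.objective_id,
            name=self.name,
            notes=copy.deepcopy(self.notes),
        )


_INF = 1e6  # bound used to encode "unbounded" in serialised models


def write_json_model(model: MetabolicModel, path) -> None:
    """Serialise in the cobrapy JSON dialect (schema version 1)."""
    genes = sorted(model.genes())
    doc = {
        "id": model.id,
        "name": model.name,
        "version": "1",
        "compartments": {},
        "metabolites": [
            {"id": m, "name": m, "compartment": m.rsplit("_", 1)[-1]}
            for m in model.metabolite_ids
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name or r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_rule,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in genes],
        "notes": model.notes,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_json_model(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    known_mets = {m["id"] for m in doc.get("metabolites", [])}
    objective_id = None
    reactions = []
    for entry in doc["reactions"]:
        unknown = set(entry["metabolites"]) - known_mets
        if unknown:
            raise ValueError(
                f"reaction {entry['id']!r} cites unknown metabolites: {sorted(unknown)}"
            )
        reactions.append(
            Reaction(
                id=entry["id"],
                stoichiometry={m: float(c) for m, c in entry["metabolites"].items()},
                lower_bound=float(entry.get("lower_bound", 0.0)),
                upper_bound=float(entry.get("upper_bound", _INF)),
                gene_rule=entry.get("gene_reaction_rule", "") or "",
                name=entry.get("name", ""),
            )
        )
        if entry.get("objective_coefficient", 0.0):
            objective_id = entry["id"]
    if objective_id is None:
        raise ValueError("model declares no objective reaction")
    return MetabolicModel(
        id=doc.get("id", "model"),
        reactions=reactions,
        objective_id=objective_id,
        name=doc.get("name", ""),
        notes=doc.get("notes", {}) or {},
    )
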