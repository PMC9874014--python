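"""Model and table I/O: JSON and SBML (level 3 + fbc) dialects.

The JSON dialect is read and written natively (cobrapy-schema
compatible); SBML goes through cobrapy/libsbml.  Gene identifiers can be
renamed into the annotation's id space via a user-supplied two-column
mapping file (e.g. mouse symbol -> human symbol) — never a network call.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .gpr import GprExpression, parse_gpr
from .model import MetabolicModel, Reaction, read_json_model, write_json_model

__all__ = [
    "read_model",
    "write_model",
    "to_cobra",
    "from_cobra",
    "load_gene_map",
    "map_gene_ids",
    "read_medium",
    "read_measured_fluxes",
]


def _dialect_for(path, dialect: str | None) -> str:
    if dialect:
        return dialect.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model dialect from {path!r}; pass dialect=")


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML export and as an
    independent solver route)."""
    import cobra

    cb = cobra.Model(model.id)
    mets = {
        m: cobra.Metabolite(m, compartment=m.rsplit("_", 1)[-1] or "c")
        for m in model.metabolite_ids
    }
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name or rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        cb.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gene_rule:
            cr.gene_reaction_rule = rxn.gene_rule
    cb.objective = model.objective_id
    return cb


def from_cobra(cb) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(cb)
    if not coeffs:
        raise ValueError("SBML model declares no objective reaction")
    objective_id = next(iter(coeffs)).id
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gene_rule=r.gene_reaction_rule or "",
            name=r.name or "",
        )
        for r in cb.reactions
    ]
    return MetabolicModel(id=cb.id or "model", reactions=reactions, objective_id=objective_id)


def read_model(path, dialect: str | None = None, gene_map=None) -> MetabolicModel:
    """Load a model from JSON or SBML; optionally rename gene ids."""
    dialect = _dialect_for(path, dialect)
    if dialect == "json":
        model = read_json_model(path)
    elif dialect == "sbml":
        import cobra

        model = from_cobra(cobra.io.read_sbml_model(str(path)))
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")
    if gene_map:
        model = map_gene_ids(model, gene_map)
    return model


def write_model(model: MetabolicModel, path, dialect: str | None = None) -> None:
    dialect = _dialect_for(path, dialect)
    if dialect == "json":
        write_json_model(model, path)
    elif dialect == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")


def load_gene_map(path) -> dict[str, str]:
    """Two-column TSV (source_id, target_id), header optional."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError("gene map needs two columns")
    first = table.iloc[0]
    if first.iloc[0].lower() in ("source_id", "source", "from"):
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def _rename(expr: GprExpression, mapping: dict[str, str]) -> GprExpression:
    if expr.op == "leaf":
        return GprExpression("leaf", gene=mapping.get(expr.gene, expr.gene))
    if expr.op == "empty":
        return expr
    return GprExpression(expr.op, children=tuple(_rename(c, mapping) for c in expr.children))


def map_gene_ids(model: MetabolicModel, mapping: dict[str, str]) -> MetabolicModel:
    out = model.copy()
    for rxn in out.reactions:
        if rxn.gene_rule:
            rxn.gene_rule = _rename(parse_gpr(rxn.gene_rule), mapping).render()
    return out


def read_medium(path) -> dict[str, float]:
    """Medium TSV with columns metabolite_id, mM."""
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["metabolite_id"].astype(str), table["mM"].astype(float)))


def read_measured_fluxes(path, condition: str | None = None) -> dict[str, float]:
    """Measured-flux TSV (condition, metabolite_id, flux[, unit]);
    returns one condition's metabolite -> signed flux map."""
    table = pd.read_csv(path, sep="\t")
    if condition is not None:
        table = table[table["condition"] == condition]
        if table.empty:
            raise ValueError(f"no measured fluxes for condition {condition!r}")
    return dict(zip(table["metabolite_id"].astype(str), table["flux"].astype(float)))
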