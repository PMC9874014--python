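"""Gene-reaction rules, the minsum aggregation, and abundance-derived bounds.

Genome-scale models attach a boolean *gene-reaction rule* to each enzymatic
reaction: ``AND`` joins obligate subunits of a complex, ``OR`` joins
isozymes that catalyse the reaction independently.  Protein abundances are
folded through that rule with the *minsum* convention — minimum over AND
members (a complex is limited by its scarcest subunit), sum over OR members
(isozyme capacities add).

The resulting effective abundance is mapped to a flux-bound magnitude
through a saturating (Michaelis-Menten-like) *compression* curve

    s(a) = a * (1 + k) / (a + k * a_max),

normalised so the most abundant reaction always maps to 1.  Small ``k``
compresses hard (any expressed enzyme gets a near-maximal bound); large
``k`` approaches the linear map ``a / a_max``.  Exchange-reaction bounds
are scaled either from growth-medium composition (DMEM mode) or from
measured uptake/secretion fluxes, in proportion ``r`` to the internal
bound scale ``b_max``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping

from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "GprError",
    "GprExpression",
    "parse_gpr",
    "minsum",
    "CompressionParams",
    "compress",
    "effective_abundances",
    "internal_bounds",
    "ExchangeSpec",
    "exchange_bounds",
]


class GprError(ValueError):
    """Raised for malformed gene-reaction rule strings."""


@dataclass(frozen=True)
class GprExpression:
    """Normalised boolean tree: ``op`` is 'and', 'or', 'leaf' or 'empty'."""

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = ()

    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        if self.op == "leaf":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def render(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "leaf":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.render()
            if child.op in ("and", "or") and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


_TOKEN = re.compile(r"\s*(\(|\)|[Aa][Nn][Dd]\b|[Oo][Rr]\b|[^\s()]+)")


def _tokenize(rule: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(rule):
        match = _TOKEN.match(rule, pos)
        if match is None:
            break
        tok = match.group(1)
        low = tok.lower()
        tokens.append(low if low in ("and", "or", "(", ")") else tok)
        pos = match.end()
    return tokens


def _flatten(op: str, children: list[GprExpression]) -> GprExpression:
    flat: list[GprExpression] = []
    for child in children:
        if child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    if len(flat) == 1:
        return flat[0]
    return GprExpression(op, children=tuple(flat))


class _Parser:
    """Recursive-descent parser; OR binds looser than AND."""

    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprError(f"unexpected end of rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse_or(self) -> GprExpression:
        children = [self.parse_and()]
        while self.peek() == "or":
            self.take()
            children.append(self.parse_and())
        return _flatten("or", children)

    def parse_and(self) -> GprExpression:
        children = [self.parse_atom()]
        while self.peek() == "and":
            self.take()
            children.append(self.parse_atom())
        return _flatten("and", children)

    def parse_atom(self) -> GprExpression:
        tok = self.take()
        if tok == "(":
            expr = self.parse_or()
            if self.take() != ")":
                raise GprError(f"unbalanced parentheses in rule {self.rule!r}")
            return expr
        if tok in (")", "and", "or"):
            raise GprError(f"unexpected token {tok!r} in rule {self.rule!r}")
        return GprExpression("leaf", gene=tok)


def parse_gpr(rule: str | None) -> GprExpression:
    """Parse a gene-reaction rule string into a normalised boolean tree."""
    if rule is None or not rule.strip():
        return GprExpression("empty")
    parser = _Parser(_tokenize(rule), rule)
    expr = parser.parse_or()
    if parser.peek() is not None:
        raise GprError(f"trailing tokens in rule {rule!r}")
    return expr


def minsum(expr: GprExpression, abundance: Mapping[str, float]) -> float:
    """Effective abundance: min over AND members, sum over OR members.

    Genes absent from ``abundance`` contribute 0 (so a complex missing a
    subunit is blocked); each absence is logged once per call site.
    """
    if expr.is_empty():
        return 0.0
    if expr.op == "leaf":
        value = abundance.get(expr.gene)
        if value is None:
            logger.debug("gene %s absent from abundance map; using 0", expr.gene)
            return 0.0
        if value < 0:
            raise ValueError(f"negative abundance for gene {expr.gene}")
        return float(value)
    parts = [minsum(child, abundance) for child in expr.children]
    return min(parts) if expr.op == "and" else sum(parts)


# ---------------------------------------------------------------------------
# abundance -> flux-bound compression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompressionParams:
    """``k``: half-saturation fraction (larger = closer to linear);
    ``b_max``: flux bound assigned to the most abundant reaction."""

    k: float
    b_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("compression k must be > 0")
        if self.b_max <= 0:
            raise ValueError("b_max must be > 0")


def compress(a: float, a_max: float, params: CompressionParams) -> float:
    """Saturating abundance->bound fraction, normalised so s(a_max) = 1."""
    if a_max <= 0:
        raise ValueError("a_max must be > 0")
    if a < 0 or a > a_max * (1 + 1e-9):
        raise ValueError("abundance must lie in [0, a_max]")
    k = params.k
    return (a / (a + k * a_max)) * (1.0 + k) if a > 0 else 0.0


def effective_abundances(
    model: MetabolicModel, abundance: Mapping[str, float]
) -> dict[str, float]:
    """minsum-aggregated abundance for every gene-associated reaction."""
    out: dict[str, float] = {}
    for rxn in model.reactions:
        expr = parse_gpr(rxn.gene_rule)
        if not expr.is_empty():
            out[rxn.id] = minsum(expr, abundance)
    return out


def internal_bounds(
    model: MetabolicModel,
    effective: Mapping[str, float],
    params: CompressionParams,
) -> MetabolicModel:
    """Set bounds of gene-associated reactions from compressed abundances.

    Upper bound = b_max * s(a); lower bound mirrors it for reversible
    reactions and stays 0 for irreversible ones.  Reactions without a
    gene rule (including exchanges) keep their default bounds, and the
    most abundant reaction is pinned at b_max for every k.
    """
    if not effective:
        return model.copy()
    a_max = max(effective.values())
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id not in effective:
            continue
        if a_max <= 0:
            bound = 0.0
        else:
            bound = params.b_max * compress(effective[rxn.id], a_max, params)
        was_reversible = rxn.lower_bound < 0
        rxn.upper_bound = bound
        rxn.lower_bound = -bound if was_reversible else 0.0
    return out


# ---------------------------------------------------------------------------
# exchange bounds
# ---------------------------------------------------------------------------

@dataclass
class ExchangeSpec:
    """How metabolite availability constrains exchange reactions.

    DMEM mode scales uptake bounds from medium molarity relative to
    glucose (25 mM reference).  Measured mode pins the measured fluxes
    after a two-step normalisation that sets every condition's glucose
    bound to -25 model units, preserving signs so secreted metabolites
    constrain efflux; unmeasured exchanges keep their DMEM scaling.
    ``r`` is the availability-to-internal-bound ratio swept on the x
    axis of the supply heatmaps.
    """

    mode: str  # "dmem" | "measured"
    medium_mM: dict[str, float]
    r: float
    measured_fluxes: dict[str, float] = field(default_factory=dict)
    glucose_id: str = "glc_e"
    glucose_reference_mM: float = 25.0
    glucose_reference_bound: float = 25.0
    secretion_constraint: str = "floor"  # floor | ceiling | equality
    #: exchanged species whose availability the medium does not set
    #: (gases, water, protons); their bounds keep the model defaults
    free_exchanges: tuple[str, ...] = ("o2_e", "h2o_e", "co2_e")

    def __post_init__(self) -> None:
        if self.mode not in ("dmem", "measured"):
            raise ValueError(f"unknown exchange mode {self.mode!r}")
        if self.r < 0:
            raise ValueError("availability ratio r must be >= 0")
        if self.glucose_id not in self.medium_mM:
            raise ValueError(f"glucose ({self.glucose_id}) missing from medium")
        if self.mode == "measured" and self.glucose_id not in self.measured_fluxes:
            raise ValueError("measured mode requires a glucose flux measurement")


def normalized_measured_fluxes(spec: ExchangeSpec) -> dict[str, float]:
    """Rescale measured fluxes so glucose uptake equals -25 model units."""
    glucose_flux = spec.measured_fluxes[spec.glucose_id]
    if glucose_flux >= 0:
        raise ValueError("measured glucose flux must be negative (uptake)")
    factor = spec.glucose_reference_bound / abs(glucose_flux)
    return {met: flux * factor for met, flux in spec.measured_fluxes.items()}


def exchange_bounds(
    model: MetabolicModel, spec: ExchangeSpec, params: CompressionParams
) -> MetabolicModel:
    """Apply availability constraints to the exchange reactions.

    DMEM: uptake lower bound of metabolite m is -r * b_max * mM_m / mM_glc;
    metabolites absent from the medium get uptake bound 0.  Measured:
    normalised fluxes are mapped through the same unit scale
    (r * b_max / 25), so glucose lands exactly at -r * b_max.
    """
    out = model.copy()
    scale = spec.r * params.b_max
    unit = scale / spec.glucose_reference_bound
    measured = normalized_measured_fluxes(spec) if spec.mode == "measured" else {}
    for rxn in out.exchanges:
        met = next(iter(rxn.stoichiometry))
        if met in spec.free_exchanges:
            continue
        if met in measured:
            value = measured[met] * unit
            if value <= 0:  # uptake: cap availability
                rxn.lower_bound = value
            else:  # secretion: constrain efflux
                if spec.secretion_constraint == "floor":
                    rxn.lower_bound = value
                elif spec.secretion_constraint == "ceiling":
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = value
                else:
                    rxn.lower_bound = rxn.upper_bound = value
        else:
            mM = spec.medium_mM.get(met, 0.0)
            glc_mM = spec.medium_mM[spec.glucose_id]
            rxn.lower_bound = -scale * mM / glc_mM if mM else 0.0
    return out
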