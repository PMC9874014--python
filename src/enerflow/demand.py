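"""Distribute the calibrated ATP/GTP capacity across energy consumers.

The demand model assumes the cell's maximum ATP (and GTP) flux is split
among all ATP/GTP-requiring enzymes in proportion to their corrected
abundance: complexes aggregated by the same min/sum rules as the supply
side, compressed with the same saturation parameter k, and weighted by
turnover number kcat where known (mean-imputed otherwise).  Summing the
resulting per-consumer fluxes by functional class yields the whole-cell
energy budget; the amino-acid-tRNA-ligase class, at 2 ATP per amino acid
activated and 110 Da per average residue, converts to a predicted
protein-synthesis rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .gpr import CompressionParams, compress, minsum, parse_gpr

__all__ = [
    "ConsumerRecord",
    "build_consumers",
    "consumers_to_frame",
    "budget",
    "ProteinSynthesisEstimate",
    "protein_synthesis",
]

#: Protein-synthesis stoichiometry: ATP spent per amino acid activated by
#: its tRNA ligase, and average residue mass.
ATP_PER_AMINO_ACID = 2.0
AMINO_ACID_MASS_DA = 110.0
DEFAULT_TURNOVER_PER_DAY = 0.5


@dataclass
class ConsumerRecord:
    consumer_id: str
    class_level1: str
    cofactor: str  # ATP | GTP
    corrected_abundance: float  # after min/sum aggregation + compression
    kcat: float  # per second; mean-imputed when unknown
    kcat_imputed: bool
    weight: float  # corrected_abundance * kcat
    share: float  # weight / total weight


def build_consumers(
    abundance: Mapping[str, float],
    ann: AnnotationTable,
    params: CompressionParams,
    complex_rules: Mapping[str, str] | None = None,
    cofactors: tuple[str, ...] = ("ATP", "GTP"),
) -> list[ConsumerRecord]:
    """Build the energy-consumer list from a complete abundance vector.

    ``abundance`` must come from the imputed (complete) proteome.
    ``complex_rules`` optionally maps a consumer id to a boolean rule over
    gene ids (AND = complex subunits, OR = isoforms); member genes are
    aggregated by min/sum and removed from the monomer pool.  Proteins
    without a complex definition act as monomers.  Compression uses the
    same k as the supply side, normalised to the most abundant consumer.
    """
    table = ann.table
    consumer_genes = table.index[table["cofactor"].isin(cofactors)]
    consumer_genes = [g for g in consumer_genes if g in abundance]

    complex_rules = dict(complex_rules or {})
    in_complex: set[str] = set()
    raw: list[tuple[str, str, str, float]] = []  # (id, class, cofactor, abundance)
    for cid, rule in complex_rules.items():
        expr = parse_gpr(rule)
        members = sorted(expr.genes())
        annotated = [g for g in members if g in table.index]
        if not annotated:
            raise ValueError(f"complex {cid!r} has no annotated member genes")
        lead = annotated[0]
        raw.append(
            (
                cid,
                str(table.at[lead, "function_level1"]),
                str(table.at[lead, "cofactor"]),
                minsum(expr, abundance),
            )
        )
        in_complex |= set(members)
    for gene in consumer_genes:
        if gene in in_complex:
            continue
        raw.append(
            (
                gene,
                str(table.at[gene, "function_level1"]),
                str(table.at[gene, "cofactor"]),
                float(abundance[gene]),
            )
        )
    raw = [r for r in raw if r[2] in cofactors]
    if not raw:
        raise ValueError("no ATP/GTP consumers found in the abundance table")

    a_max = max(value for *_, value in raw)
    corrected = [
        compress(value, a_max, params) if a_max > 0 else 0.0 for *_, value in raw
    ]

    # kcat: per consumer via its (lead) gene; missing -> mean of known kcats
    # within the same cofactor pool
    kcats = []
    for (cid, _, _, _) in raw:
        genes = sorted(parse_gpr(complex_rules[cid]).genes()) if cid in complex_rules else [cid]
        values = [table.at[g, "kcat"] for g in genes if g in table.index]
        values = [v for v in values if np.isfinite(v)]
        kcats.append(float(np.mean(values)) if values else np.nan)
    kcats = np.asarray(kcats, dtype=float)
    imputed_mask = ~np.isfinite(kcats)
    cof_arr = np.array([r[2] for r in raw])
    for cof in set(cof_arr):
        pool = np.isfinite(kcats) & (cof_arr == cof)
        mean_kcat = float(kcats[pool].mean()) if pool.any() else float("nan")
        if not np.isfinite(mean_kcat):
            known = kcats[np.isfinite(kcats)]
            mean_kcat = float(known.mean()) if known.size else 1.0
        kcats[(cof_arr == cof) & ~np.isfinite(kcats)] = mean_kcat

    weights = np.array(corrected) * kcats
    total = weights.sum()
    if total <= 0:
        raise ValueError("total consumer weight is zero")
    records = []
    for (cid, cls, cof, _), corr, kc, imp, w in zip(raw, corrected, kcats, imputed_mask, weights):
        records.append(
            ConsumerRecord(
                consumer_id=cid,
                class_level1=cls,
                cofactor=cof,
                corrected_abundance=float(corr),
                kcat=float(kc),
                kcat_imputed=bool(imp),
                weight=float(w),
                share=float(w / total),
            )
        )
    return records


def consumers_to_frame(consumers: list[ConsumerRecord]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in consumers]).set_index("consumer_id")


def budget(
    consumers: list[ConsumerRecord],
    total_capacity: float,
    cofactor_filter: tuple[str, ...] | None = None,
    total_expression: float | None = None,
) -> pd.DataFrame:
    """Per-class energy budget at a calibration point.

    Returns classes sorted by descending flux with columns
    ``expression_pct`` (percent of total kcat-corrected expression — by
    default the consumer total, or of all proteins when
    ``total_expression`` is given), ``flux`` (total_capacity x summed
    consumer shares, in the capacity's units) and ``cumulative_frac``
    (fraction of total demand covered down to that row, for the
    90%-coverage cut).
    """
    if total_capacity < 0:
        raise ValueError("total capacity must be >= 0")
    frame = consumers_to_frame(consumers)
    if cofactor_filter is not None:
        frame = frame[frame["cofactor"].isin(cofactor_filter)]
    denom = total_expression if total_expression is not None else frame["weight"].sum()
    by_class = frame.groupby("class_level1").agg(
        share=("share", "sum"), weight=("weight", "sum"), cofactor=("cofactor", "first")
    )
    by_class["expression_pct"] = 100.0 * by_class["weight"] / denom
    by_class["flux"] = total_capacity * by_class["share"]
    by_class = by_class.sort_values("flux", ascending=False, kind="mergesort")
    total_flux = by_class["flux"].sum()
    by_class["cumulative_frac"] = (
        by_class["flux"].cumsum() / total_flux if total_flux > 0 else 0.0
    )
    by_class.attrs["total_capacity"] = float(total_capacity)
    return by_class[["cofactor", "expression_pct", "share", "flux", "cumulative_frac"]]


@dataclass
class ProteinSynthesisEstimate:
    """Rates in per-day units of the protein pool (mass fraction)."""

    atp_to_ligases: float  # pmol ATP / ng protein / day
    aa_flux: float  # pmol amino acid / ng protein / day
    total_rate: float  # /day: mass fraction of protein pool synthesised
    net_rate: float  # /day: total minus turnover
    turnover_rate: float


def protein_synthesis(
    budget_frame: pd.DataFrame,
    turnover_rate: float = DEFAULT_TURNOVER_PER_DAY,
    ligase_class: str | None = None,
) -> ProteinSynthesisEstimate:
    """Protein-synthesis rate from the tRNA-ligase class ATP flux.

    aa_flux = ligase ATP flux / 2 (two ATP per activated amino acid);
    total rate = aa_flux * 110 pg/pmol / 1000 (pg -> ng protein), giving
    the mass fraction of the protein pool synthesised per day; net rate
    subtracts the assumed turnover.
    """
    if ligase_class is None:
        matches = [c for c in budget_frame.index if "tRNA ligase" in c]
        if not matches:
            raise ValueError("no amino-acid-tRNA-ligase class in budget")
        ligase_class = matches[0]
    elif ligase_class not in budget_frame.index:
        raise ValueError(f"ligase class {ligase_class!r} absent from budget")
    atp_to_ligases = float(budget_frame.at[ligase_class, "flux"])
    aa_flux = atp_to_ligases / ATP_PER_AMINO_ACID
    total_rate = aa_flux * AMINO_ACID_MASS_DA / 1000.0  # pg per pmol, per ng protein
    return ProteinSynthesisEstimate(
        atp_to_ligases=atp_to_ligases,
        aa_flux=aa_flux,
        total_rate=total_rate,
        net_rate=total_rate - turnover_rate,
        turnover_rate=turnover_rate,
    )
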