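"""Energy-centric functional ontology: annotations, class sums, rankings.

Each protein-coding gene carries one dominant subcellular localization,
a fine (level-1) and a coarse (level-2) functional class, the high-energy
cofactor its catalytic activity consumes (ATP/GTP/CTP or a reducing
equivalent), a tissue-expression category from the Human Protein Atlas,
and optionally a turnover number (kcat).  The localization and class
vocabularies are data, loaded with the annotation file; the
tissue-expression categories form a closed set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .proteome import ProteomeTable

__all__ = [
    "HPA_CATEGORIES",
    "COFACTORS",
    "LOCALIZATIONS",
    "AnnotationTable",
    "load_annotation",
    "merge_localizations",
    "class_sums",
    "TiePolicy",
    "rank_groups",
]

HPA_CATEGORIES = (
    "Detected in all",
    "Detected in many",
    "Detected in some",
    "Detected in single",
    "Not detected",
    "#N/A",
)

COFACTORS = ("ATP", "GTP", "CTP", "NAD", "NADP", "none")

#: The 19 merged dominant subcellular localizations.
LOCALIZATIONS = (
    "Extracellular",
    "Cell ECM junctions",
    "Cell cell junctions",
    "Cell membrane",
    "Cytosol",
    "Ribosomes",
    "Endoplasmic reticulum",
    "Golgi apparatus",
    "Mitochondria",
    "Lysosomes",
    "Peroxisomes",
    "Other vesicles",
    "Microfilaments",
    "Cilia, centrosome",
    "Cell Cortex",
    "Focal adhesion sites",
    "Proteasome",
    "Nucleus",
    "UNKNOWN",
)

_COLUMNS = ["localization", "function_level1", "function_level2", "cofactor", "hpa_category", "kcat"]


@dataclass
class AnnotationTable:
    """Gene-level annotation; index is gene_id, one row per gene."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dupes}")
        for col in _COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan if col == "kcat" else "none"
        bad = set(self.table["hpa_category"].dropna()) - set(HPA_CATEGORIES)
        if bad:
            raise ValueError(f"unknown tissue-expression category values: {sorted(bad)}")
        cof = self.table["cofactor"].fillna("none")
        bad = set(cof) - set(COFACTORS)
        if bad:
            raise ValueError(f"unknown cofactor values: {sorted(bad)}")
        self.table["cofactor"] = cof
        self.table["kcat"] = pd.to_numeric(self.table["kcat"], errors="coerce")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def column_for(self, gene_ids, column: str, default):
        """Annotation column aligned to ``gene_ids``; missing genes get ``default``."""
        series = self.table[column].reindex(gene_ids)
        return series.fillna(default) if default is not None else series

    def hpa_category(self, gene_id: str) -> str:
        if gene_id in self.table.index:
            value = self.table.at[gene_id, "hpa_category"]
            if isinstance(value, str) and value in HPA_CATEGORIES:
                return value
        return "#N/A"  # unannotated proteins default to the unknown category

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="")


def load_annotation(path) -> AnnotationTable:
    """Read and validate an annotation TSV (gene_id + annotation columns)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in table.columns:
        raise ValueError("annotation file lacks a gene_id column")
    table = table.set_index("gene_id")
    missing = [c for c in ("localization", "function_level1", "hpa_category") if c not in table.columns]
    if missing:
        raise ValueError(f"annotation file lacks required columns: {missing}")
    return AnnotationTable(table)


def merge_localizations(localizations: pd.Series, mapping_path=None) -> pd.Series:
    """Collapse fine-grained localization labels to the 19 merged groups.

    The mapping ships as an editable TSV fixture (fine_label -> merged
    group); labels absent from the mapping pass through unchanged.
    """
    if mapping_path is None:
        ref = resources.files("enerflow.data").joinpath("localization_merge.tsv")
        with resources.as_file(ref) as p:
            mapping = pd.read_csv(p, sep="\t").set_index("fine_label")["merged_group"]
    else:
        mapping = pd.read_csv(mapping_path, sep="\t").set_index("fine_label")["merged_group"]
    return localizations.map(lambda x: mapping.get(x, x))


_GROUPING_COLUMN = {
    "localization": "localization",
    "level1": "function_level1",
    "level2": "function_level2",
    "cofactor": "cofactor",
}


def class_sums(
    proteome: ProteomeTable, ann: AnnotationTable, grouping: str
) -> pd.DataFrame:
    """Per-group, per-sample abundance sums (groups x samples).

    Missing abundances contribute nothing; proteins without annotation
    fall into an "UNKNOWN" group.  Groups are ordered by descending
    grand mean.  Cofactor grouping drops the "none" group (only
    energy-consuming proteins are of interest there).
    """
    if proteome.data.empty:
        raise ValueError("empty proteome")
    column = _GROUPING_COLUMN[grouping]
    labels = ann.column_for(proteome.data.index, column, "UNKNOWN")
    sums = proteome.data.groupby(labels.to_numpy()).sum(min_count=0)
    if grouping == "cofactor" and "none" in sums.index:
        sums = sums.drop(index="none")
    order = sums.mean(axis=1).sort_values(ascending=False).index
    out = sums.loc[order]
    out.index.name = grouping
    return out


@dataclass
class TiePolicy:
    """When two conditions' sums count as tied.

    ``threshold``: relative difference below which sums share a rank
    (stands in for a post-hoc significance call).  ``significant`` may
    supply an externally computed boolean matrix (conditions x
    conditions, True = significantly different) that overrides the
    threshold.
    """

    threshold: float = 0.05
    significant: pd.DataFrame | None = None

    def tied(self, cond_a: str, a: float, cond_b: str, b: float) -> bool:
        if self.significant is not None:
            return not bool(self.significant.loc[cond_a, cond_b])
        scale = max(abs(a), abs(b))
        if scale == 0:
            return True
        return abs(a - b) <= self.threshold * scale


def rank_groups(sums: pd.DataFrame, tie_policy: TiePolicy | None = None) -> pd.DataFrame:
    """Rank conditions within each group (rank 1 = largest sum).

    ``sums`` is groups x conditions.  Conditions whose sums are tied
    under the policy share the average of their positions (two tied
    leaders both get 1.5).  Tie chaining is transitive along the sorted
    order.
    """
    if sums.shape[1] < 2:
        raise ValueError("ranking needs at least two conditions")
    tie_policy = tie_policy or TiePolicy()
    ranks = pd.DataFrame(index=sums.index, columns=sums.columns, dtype=float)
    for group, row in sums.iterrows():
        order = row.sort_values(ascending=False)
        conds, values = list(order.index), order.to_numpy(dtype=float)
        position = 0
        while position < len(conds):
            end = position
            while end + 1 < len(conds) and tie_policy.tied(
                conds[end], values[end], conds[end + 1], values[end + 1]
            ):
                end += 1
            shared = np.mean(np.arange(position, end + 1)) + 1.0
            for idx in range(position, end + 1):
                ranks.at[group, conds[idx]] = shared
            position = end + 1
    return ranks
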