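"""Protein-abundance table with explicit missingness.

Label-free (LFQ-style) intensities, proteins x samples, with NaN marking
values the mass spectrometer did not report.  Metadata columns carry the
energy-ontology labels used downstream (functional class levels,
localization, tissue-expression category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProteomeTable", "META_COLUMNS"]

META_COLUMNS = ["class_level1", "class_level2", "localization", "hpa_category"]


@dataclass
class ProteomeTable:
    """``data``: abundances (index protein_id, one column per sample, NaN =
    missing); ``meta``: per-protein annotation aligned on the same index."""

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein ids in proteome")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=self.data.index.copy())
        elif not self.meta.index.equals(self.data.index):
            self.meta = self.meta.reindex(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "ProteomeTable":
        return ProteomeTable(self.data.copy(), self.meta.copy())

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write metadata + sample columns; missing encoded as empty field."""
        out = pd.concat([self.meta, self.data], axis=1)
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "ProteomeTable":
        table = pd.read_csv(path, sep="\t", index_col="protein_id")
        meta_cols = [c for c in META_COLUMNS if c in table.columns]
        sample_cols = [c for c in table.columns if c not in meta_cols]
        data = table[sample_cols].astype(float)
        return cls(data=data, meta=table[meta_cols])
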