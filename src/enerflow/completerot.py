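"""Rule-based missing-value imputation for label-free proteomes.

Shotgun LFQ datasets miss a sizeable fraction of proteins per run.  This
module fills each missing value from the detected members of the
protein's functional class, choosing the statistic by the protein's
tissue-expression category (Human Protein Atlas style):

    Detected in all    -> class average
    Detected in many   -> class minimum
    Detected in some   -> class minimum
    Detected in single -> class minimum
    Not detected       -> zero
    #N/A               -> class minimum

The rationale: a ubiquitously expressed protein that is missing was
almost surely present near the typical class level (average); a protein
of restricted expression, if present at all, is likely near the class
floor (minimum); a protein not detected in any tissue is treated as
genuinely absent (zero).

Statistics are computed per sample (column-wise) over observed values
only; class minima ignore zeros.  When the level-1 class has no detected
member in a sample, the cascade falls back to the level-2 class and then
to the whole table (level 3); if even that fails, a global fallback of 0
is used and flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .proteome import ProteomeTable

__all__ = ["CATEGORY_RULES", "ImputationReport", "impute", "compare_prepost"]

CATEGORY_RULES = {
    "Detected in all": "average",
    "Detected in many": "minimum",
    "Detected in some": "minimum",
    "Detected in single": "minimum",
    "Not detected": "zero",
    "#N/A": "minimum",
}


@dataclass
class ImputationReport:
    """One row per originally missing entry."""

    protein_id: str
    sample: str
    rule_applied: str  # average | minimum | zero
    source_class: str
    source_level: str  # level1 | level2 | level3 | fallback
    value: float


def _class_statistics(
    observed: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class per-sample mean and (zero-free) minimum of observed values."""
    grouped = observed.groupby(labels.to_numpy())
    means = grouped.mean()
    minima = observed.where(observed > 0).groupby(labels.to_numpy()).min()
    return means, minima


def impute(
    proteome: ProteomeTable, ann: AnnotationTable
) -> tuple[ProteomeTable, list[ImputationReport]]:
    """Fill every missing value per the category rules; observed values
    are never altered.  Returns the completed table and a per-entry report."""
    data = proteome.data
    completed = data.copy()
    index = data.index

    categories = pd.Series([ann.hpa_category(p) for p in index], index=index)
    level1 = ann.column_for(index, "function_level1", "UNKNOWN")
    level2 = ann.column_for(index, "function_level2", "UNKNOWN")

    stats = {
        "level1": (_class_statistics(data, level1), level1),
        "level2": (_class_statistics(data, level2), level2),
    }
    whole_mean = data.mean()
    whole_min = data.where(data > 0).min()

    reports: list[ImputationReport] = []
    missing_rows, missing_cols = np.where(data.isna().to_numpy())
    columns = list(data.columns)
    for row, col in zip(missing_rows, missing_cols):
        protein = index[row]
        sample = columns[col]
        rule = CATEGORY_RULES[categories.iloc[row]]
        if rule == "zero":
            value, source_class, source_level = 0.0, "", "level1"
        else:
            value, source_class, source_level = np.nan, "", ""
            for level in ("level1", "level2"):
                (means, minima), labels = stats[level]
                cls = labels.iloc[row]
                table = means if rule == "average" else minima
                if cls in table.index:
                    candidate = table.at[cls, sample]
                    if np.isfinite(candidate):
                        value, source_class, source_level = float(candidate), cls, level
                        break
            if not np.isfinite(value):
                candidate = whole_mean[sample] if rule == "average" else whole_min[sample]
                if np.isfinite(candidate):
                    value, source_class, source_level = float(candidate), "ALL", "level3"
                else:
                    value, source_class, source_level = 0.0, "ALL", "fallback"
        completed.iat[row, col] = value
        reports.append(
            ImputationReport(
                protein_id=str(protein),
                sample=str(sample),
                rule_applied=rule,
                source_class=source_class,
                source_level=source_level,
                value=value,
            )
        )
    return ProteomeTable(completed, proteome.meta.copy()), reports


def reports_to_frame(reports: list[ImputationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def compare_prepost(
    proteome: ProteomeTable,
    completed: ProteomeTable,
    ann: AnnotationTable,
    grouping: str = "level2",
) -> tuple[pd.DataFrame, float]:
    """Per-group sums before/after imputation and their Pearson correlation.

    The correlation is over all (group, sample) pairs.  With a single
    group (or zero variance) it is undefined and reported as NaN.
    """
    from .annotation import class_sums

    before = class_sums(proteome, ann, grouping)
    after = class_sums(completed, ann, grouping)
    after = after.reindex(index=before.index, columns=before.columns)
    paired = pd.concat(
        {"before": before.stack(), "after": after.stack()}, axis=1
    ).reset_index(names=[grouping, "sample"])
    x = paired["before"].to_numpy(dtype=float)
    y = paired["after"].to_numpy(dtype=float)
    if len(before.index) < 2 or np.std(x) == 0 or np.std(y) == 0:
        corr = float("nan")
    elif np.allclose(x, y):
        corr = 1.0
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    return paired, corr
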