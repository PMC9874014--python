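"""Category-rule imputation: the six rules, cascade, and recovery."""

import io

import numpy as np
import pandas as pd
import pytest

from conftest import annotation_from_meta
from enerflow.annotation import load_annotation
from enerflow.completerot import CATEGORY_RULES, compare_prepost, impute, reports_to_frame
from enerflow.proteome import ProteomeTable
from enerflow.synthetic import SyntheticProteomeSpec, make_synthetic_proteome

ANN_HEADER = "gene_id\tlocalization\tfunction_level1\tfunction_level2\tcofactor\thpa_category\tkcat\n"


def _setup(category: str, class_values=(10.0, 30.0)):
    rows = "".join(
        f"d{i}\tCytosol\tF1\tG1\tnone\tDetected in all\t\n" for i in range(len(class_values))
    )
    rows += f"miss\tCytosol\tF1\tG1\tnone\t{category}\t\n"
    ann = load_annotation(io.StringIO(ANN_HEADER + rows))
    data = pd.DataFrame(
        {f"d{i}": [v] for i, v in enumerate(class_values)} | {"miss": [np.nan]},
        index=["s1"],
    ).T
    data.index.name = "protein_id"
    return ProteomeTable(data), ann


class TestCategoryRules:
    @pytest.mark.parametrize(
        "category,expected,rule",
        [
            ("Detected in all", 20.0, "average"),
            ("Detected in many", 10.0, "minimum"),
            ("Detected in some", 10.0, "minimum"),
            ("Detected in single", 10.0, "minimum"),
            ("Not detected", 0.0, "zero"),
            ("#N/A", 10.0, "minimum"),
        ],
    )
    def test_all_six_rules(self, category, expected, rule):
        prot, ann = _setup(category)
        completed, reports = impute(prot, ann)
        assert completed.data.at["miss", "s1"] == expected
        assert len(reports) == 1
        assert reports[0].rule_applied == rule
        assert CATEGORY_RULES[category] == rule

    def test_minimum_ignores_zeros(self):
        prot, ann = _setup("Detected in many", class_values=(0.0, 10.0, 30.0))
        completed, _ = impute(prot, ann)
        assert completed.data.at["miss", "s1"] == 10.0

    def test_unannotated_protein_uses_na_rule(self):
        prot, ann = _setup("Detected in all")
        orphan = prot.data.copy()
        orphan.loc["orphan"] = np.nan
        completed, reports = impute(ProteomeTable(orphan), ann)
        frame = reports_to_frame(reports)
        row = frame[frame.protein_id == "orphan"].iloc[0]
        assert row.rule_applied == "minimum"  # "#N/A" default
        assert row.source_level == "level3"  # no class: whole-table fallback


class TestCascade:
    def test_falls_back_to_level2_then_whole_table(self):
        rows = (
            "a\tCytosol\tF1\tG1\tnone\tDetected in all\t\n"  # missing, class F1 empty
            "b\tCytosol\tF2\tG1\tnone\tDetected in all\t\n"  # detected, same level2
            "c\tCytosol\tF3\tG2\tnone\tDetected in all\t\n"  # detected, other level2
        )
        ann = load_annotation(io.StringIO(ANN_HEADER + rows))
        data = pd.DataFrame({"a": [np.nan], "b": [8.0], "c": [100.0]}, index=["s1"]).T
        data.index.name = "protein_id"
        completed, reports = impute(ProteomeTable(data), ann)
        assert completed.data.at["a", "s1"] == 8.0
        assert reports[0].source_level == "level2"
        # remove the level-2 sibling: falls back to whole table
        data2 = data.drop(index="b")
        completed2, reports2 = impute(ProteomeTable(data2), ann)
        assert reports2[0].source_level == "level3"
        assert completed2.data.at["a", "s1"] == 100.0

    def test_statistics_are_per_sample(self):
        rows = (
            "a\tCytosol\tF1\tG1\tnone\tDetected in all\t\n"
            "b\tCytosol\tF1\tG1\tnone\tDetected in all\t\n"
            "c\tCytosol\tF1\tG1\tnone\tDetected in all\t\n"
        )
        ann = load_annotation(io.StringIO(ANN_HEADER + rows))
        data = pd.DataFrame(
            {"a": [np.nan, np.nan], "b": [10.0, 100.0], "c": [20.0, 200.0]},
            index=["s1", "s2"],
        ).T
        data.index.name = "protein_id"
        completed, _ = impute(ProteomeTable(data), ann)
        assert completed.data.at["a", "s1"] == 15.0
        assert completed.data.at["a", "s2"] == 150.0


@pytest.fixture(scope="module")
def synthetic():
    masked, truth = make_synthetic_proteome(SyntheticProteomeSpec(seed=1))
    ann = annotation_from_meta(masked)
    completed, reports = impute(masked, ann)
    return masked, truth, ann, completed, reports


class TestInvariants:
    def test_no_missing_after(self, synthetic):
        _, _, _, completed, _ = synthetic
        assert completed.n_missing() == 0

    def test_one_report_per_missing_entry(self, synthetic):
        masked, _, _, _, reports = synthetic
        assert len(reports) == masked.n_missing()

    def test_observed_entries_bit_identical(self, synthetic):
        masked, _, _, completed, _ = synthetic
        observed = ~masked.data.isna()
        assert (
            masked.data.to_numpy()[observed.to_numpy()]
            == completed.data.to_numpy()[observed.to_numpy()]
        ).all()

    def test_idempotence(self, synthetic):
        _, _, ann, completed, _ = synthetic
        again, reports = impute(completed, ann)
        assert not reports
        pd.testing.assert_frame_equal(again.data, completed.data)

    def test_group_sums_never_shrink(self, synthetic):
        masked, _, ann, completed, _ = synthetic
        from enerflow.annotation import class_sums

        before = class_sums(masked, ann, "level1")
        after = class_sums(completed, ann, "level1").reindex(before.index)
        assert ((after - before) >= -1e-9).all().all()


class TestParameterRecovery:
    def test_class_means_recovered_within_tolerance(self):
        """Synthetic proteome, 1000 proteins, ~20% masking: imputed class
        means land within 25% of the truth class means (tolerance fixed
        from the measured error, ~19% at this seed)."""
        masked, truth = make_synthetic_proteome(SyntheticProteomeSpec(seed=1))
        ann = annotation_from_meta(masked)
        completed, _ = impute(masked, ann)
        keep = (masked.meta["hpa_category"] != "Not detected").to_numpy()
        labels = truth.meta.loc[keep, "class_level1"].to_numpy()
        t_means = truth.data[keep].groupby(labels).mean().mean(axis=1)
        i_means = completed.data[keep].groupby(labels).mean().mean(axis=1)
        rel_err = ((i_means - t_means) / t_means).abs()
        assert rel_err.max() < 0.25

    def test_not_detected_recovered_as_zero(self):
        masked, truth = make_synthetic_proteome(SyntheticProteomeSpec(seed=1))
        ann = annotation_from_meta(masked)
        completed, _ = impute(masked, ann)
        nd = (masked.meta["hpa_category"] == "Not detected").to_numpy()
        assert (completed.data[nd] == 0.0).all().all()
        assert (truth.data[nd] == 0.0).all().all()

    @pytest.mark.parametrize("seed", [11, 23])
    def test_average_rule_error_shrinks_with_class_size(self, seed):
        """Mean absolute log-error of class-average imputations against the
        population class mean decreases as the class grows."""
        mu = np.log(1e5)
        popmean = np.exp(mu + 0.8**2 / 2)  # log-normal mean at noise_sd=0.8
        errors = []
        for n in (5, 20, 80):
            spec = SyntheticProteomeSpec(
                n_classes=6, proteins_per_class=n, class_log_means=np.full(6, mu), seed=seed
            )
            masked, _ = make_synthetic_proteome(spec)
            ann = annotation_from_meta(masked)
            _, reports = impute(masked, ann)
            vals = [r.value for r in reports if r.rule_applied == "average" and r.value > 0]
            errors.append(np.mean([abs(np.log(v / popmean)) for v in vals]))
        assert errors[0] > errors[1] > errors[2]


class TestComparePrepost:
    def test_identity_without_missing(self, synthetic_complete=None):
        masked, truth = make_synthetic_proteome(
            SyntheticProteomeSpec(
                n_classes=4,
                proteins_per_class=10,
                missing_frac_by_category={c: 0.0 for c in CATEGORY_RULES},
                seed=2,
            )
        )
        ann = annotation_from_meta(masked)
        completed, _ = impute(masked, ann)
        _, corr = compare_prepost(masked, completed, ann, "level1")
        assert corr == 1.0

    def test_single_group_undefined(self):
        masked, _ = make_synthetic_proteome(
            SyntheticProteomeSpec(n_classes=1, proteins_per_class=20, seed=2)
        )
        ann = annotation_from_meta(masked)
        completed, _ = impute(masked, ann)
        _, corr = compare_prepost(masked, completed, ann, "level1")
        assert np.isnan(corr)

    def test_high_correlation_on_synthetic_masking(self):
        masked, _ = make_synthetic_proteome(SyntheticProteomeSpec(seed=1))
        ann = annotation_from_meta(masked)
        completed, _ = impute(masked, ann)
        paired, corr = compare_prepost(masked, completed, ann, "level2")
        assert corr > 0.95
        assert {"before", "after"} <= set(paired.columns)
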