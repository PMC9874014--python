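import numpy as np
import pytest

from enerflow.annotation import AnnotationTable
from enerflow.completerot import impute
from enerflow.synthetic import ToyModelSpec, make_toy_model, toy_bundle


def annotation_from_meta(proteome) -> AnnotationTable:
    """Build an annotation table directly from a synthetic proteome's
    metadata (class labels become functional classes)."""
    table = proteome.meta.copy()
    table["function_level1"] = table.pop("class_level1")
    table["function_level2"] = table["class_level2"]
    return AnnotationTable(table.rename_axis("gene_id"))


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(ToyModelSpec())


@pytest.fixture(scope="session")
def bundle():
    return toy_bundle(seed=1)


@pytest.fixture(scope="session")
def completed_bundle(bundle):
    completed, reports = impute(bundle.proteome, bundle.annotation)
    return completed, reports


@pytest.fixture(scope="session")
def bundle_abundance(completed_bundle):
    completed, _ = completed_bundle
    return completed.data.mean(axis=1).to_dict()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
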