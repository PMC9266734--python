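import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from penmark.datatypes import AnalysisConfig, CtTable, SampleAnnotation
from penmark.pipeline import quantify
from penmark.simulate import simulate_from_paper_shape

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
settings.load_profile("suite")


def make_annotation(samples, groups, **extra) -> SampleAnnotation:
    base = dict(
        sample_id=list(samples),
        group=list(groups),
        os_time=1.0,
        os_event=0,
        css_time=1.0,
        css_event=0,
    )
    base.update(extra)
    return SampleAnnotation(pd.DataFrame(base))


def make_ct(records) -> CtTable:
    """records: (sample, assay, assay_class, replicate, ct)."""
    return CtTable(
        pd.DataFrame(
            records,
            columns=["sample_id", "assay_id", "assay_class", "replicate_index", "ct"],
        )
    )


def aggregated_ct_from_matrix(values: pd.DataFrame, assay_class: str) -> CtTable:
    """samples x assays CT matrix -> aggregated long CtTable."""
    long = values.rename_axis("sample_id").reset_index().melt(
        id_vars="sample_id", var_name="assay_id", value_name="ct"
    )
    long["assay_class"] = assay_class
    long["replicate_index"] = 1
    return CtTable(
        long[["sample_id", "assay_id", "assay_class", "replicate_index", "ct"]],
        aggregated=True,
    )


@pytest.fixture(scope="session")
def paper_cohort():
    return simulate_from_paper_shape(seed=7)


@pytest.fixture(scope="session")
def paper_quant(paper_cohort):
    ct, ann, _ = paper_cohort
    mrna, mirna, stability, refs = quantify(ct, ann, AnalysisConfig())
    return mrna, mirna, stability, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
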