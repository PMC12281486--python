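import numpy as np
import pandas as pd
import pytest

from palscout.io_tables import AbundanceMatrix, MetaboliteTable, SampleDesign


@pytest.fixture
def pal_design() -> SampleDesign:
    """Three-arm design with two paired replicates per condition."""
    rows = []
    for cond in ("vehicle", "probe", "competition"):
        for r in (1, 2):
            rows.append((f"{cond}_{r}", cond, r, "biological"))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "condition",
                                    "replicate_index", "role"])
    )


@pytest.fixture
def metabo_design() -> SampleDesign:
    rows = [
        ("g1", "GFP", 1, "biological"),
        ("g2", "GFP", 2, "biological"),
        ("g3", "GFP", 3, "biological"),
        ("s1", "SCCPDH", 1, "biological"),
        ("s2", "SCCPDH", 2, "biological"),
        ("s3", "SCCPDH", 3, "biological"),
        ("qc1", "pooled_qc", 1, "pooled_qc"),
        ("qc2", "pooled_qc", 2, "pooled_qc"),
        ("qc3", "pooled_qc", 3, "pooled_qc"),
    ]
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "condition",
                                    "replicate_index", "role"])
    )


def make_matrix(values, features=None, samples=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i+1}" for i in range(values.shape[1])]
    return AbundanceMatrix(
        pd.DataFrame(values, index=features, columns=samples), scale=scale
    )


def make_metabolite_table(values, design, levels=None, features=None):
    samples = design.sample_ids
    m = make_matrix(values, features=features, samples=samples)
    ann = None
    if levels is not None:
        ann = pd.DataFrame(
            {"annotation_level": levels}, index=m.feature_ids
        )
    return MetaboliteTable(m, ann)
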