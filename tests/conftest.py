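import numpy as np
import pandas as pd
import pytest

from evip2 import (
    ExpressionMatrix,
    SampleAnnotation,
    Comparison,
    Program,
    SimSpec,
    VariantImpactModel,
    generate_experiment,
)
from evip2.synthetic import scenario_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def tiny_tpm():
    """3-gene x 4-sample TPM matrix with easy hand-checkable values."""
    df = pd.DataFrame(
        {
            "s1": [1.0, 0.5, 10.0],
            "s2": [3.0, 0.5, 20.0],
            "s3": [0.0, 0.5, 30.0],
            "s4": [7.0, 0.5, 40.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df, "tpm")


def write_tpm(path, df):
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(df.columns) + "\n")
        for g, row in df.iterrows():
            fh.write(g + "\t" + "\t".join(str(v) for v in row) + "\n")
    return path


@pytest.fixture(scope="session")
def scenario_fits():
    """Fitted results for the four canonical single-comparison scenarios."""
    out = {}
    for kind in ("neutral", "lof", "gof", "cof"):
        _, tpm, annot = generate_experiment(scenario_spec(kind, seed=7))
        out[kind] = VariantImpactModel.from_tpm(tpm, annot).fit()
    return out


@pytest.fixture(scope="session")
def null_experiment():
    """A 12-replicate single-condition null experiment (no programs)."""
    spec = SimSpec(
        n_genes=1000, conditions={"null": 12}, comparisons=[], seed=4242
    )
    return generate_experiment(spec)


def make_annotation(n_ctrl=4, n_wt=4, n_mut=4):
    mapping = {}
    for cond, n in (("control", n_ctrl), ("WT", n_wt), ("MUT", n_mut)):
        for i in range(n):
            mapping[f"{cond}_r{i + 1}"] = cond
    return SampleAnnotation(mapping, [Comparison("control", "WT", "MUT")])
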