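import numpy as np
import pandas as pd
import pytest

from crossfactor.io import ExpressionBundle


def make_design(r: int = 4) -> pd.DataFrame:
    rows = []
    cells = [("control", "control"), ("control", "treated"),
             ("treated", "control"), ("treated", "treated")]
    for ci, (f1, f2) in enumerate(cells):
        for rep in range(1, r + 1):
            rows.append(
                {"sample_id": f"s{ci * r + rep:02d}", "factor1": f1,
                 "factor2": f2, "replicate": rep}
            )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def toy_design() -> pd.DataFrame:
    return make_design(4)


@pytest.fixture
def toy_bundle(toy_design) -> ExpressionBundle:
    """4 probesets x 16 samples with distinct flat per-cell levels."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(50, 500, size=(4, 16)),
        index=[f"p{i}" for i in range(4)],
        columns=list(toy_design.index),
    )
    return ExpressionBundle(values=values, design=toy_design)


def write_matrix_and_sheet(tmp_path, values: pd.DataFrame, design: pd.DataFrame):
    matrix = tmp_path / "matrix.tsv"
    sheet = tmp_path / "samples.tsv"
    values.rename_axis("probeset_id").to_csv(matrix, sep="\t")
    design.reset_index().to_csv(sheet, sep="\t", index=False)
    return matrix, sheet
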