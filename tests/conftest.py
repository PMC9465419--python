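import numpy as np
import pandas as pd
import pytest

from nesubtype import (
    ExpressionMatrix,
    GenePair,
    LabelTable,
    Signature,
    load_builtin_panel,
)

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


def make_matrix(values: dict[str, dict[str, float]]) -> ExpressionMatrix:
    """Build a small matrix from {sample: {gene: value}} (NaN for missing)."""
    return ExpressionMatrix(pd.DataFrame(values))


@pytest.fixture(scope="session")
def builtin_panel():
    return load_builtin_panel()


@pytest.fixture(scope="session")
def table1_fixture() -> pd.DataFrame:
    """Independent transcription of the 92-pair panel, for integrity checks."""
    return pd.read_csv(f"{DATA_DIR}/table1_pairs.tsv", sep="\t", dtype=str)


@pytest.fixture
def toy_signature() -> Signature:
    pairs = [GenePair(f"A{i}", f"B{i}", positive_class="pos") for i in range(1, 6)]
    return Signature("toy", pairs, positive_label="pos", negative_label="neg")


def panel_archetype_values(panel, route: str) -> dict[str, float]:
    """Sample values realizing a pure decision path of a panel.

    ``route`` is a comma-separated chain of per-signature outcomes in step
    order, e.g. ``"GT,LE,GT"``; later steps not named default to LE.
    """
    outcomes = route.split(",")
    values: dict[str, float] = {}
    for i, step in enumerate(panel.steps):
        want_gt = i < len(outcomes) and outcomes[i] == "GT"
        for pair in step.signature.pairs:
            values[pair.gene_a] = 2.0 if want_gt else 1.0
            values[pair.gene_b] = 1.5
    return values
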