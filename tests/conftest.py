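import numpy as np
import pandas as pd
import pytest

from stereoquant.types import QuantMatrix, StudyDesign


@pytest.fixture
def five_fraction_design() -> StudyDesign:
    labels = ["S1", "P2", "M3", "P6", "S7"]
    return StudyDesign(fraction_order=labels, sample_fraction={f: f for f in labels})


@pytest.fixture
def random_ibaq() -> QuantMatrix:
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(
        10.0 ** rng.normal(6, 1, size=(50, 5)),
        index=[f"P{i:03d}" for i in range(50)],
        columns=["S1", "P2", "M3", "P6", "S7"],
    )
    cont = pd.Series(False, index=vals.index)
    cont.iloc[:5] = True
    return QuantMatrix(vals, contaminant=cont)


def quant(values, columns=None, **kw) -> QuantMatrix:
    """Small helper to build a QuantMatrix from a dict/array."""
    df = pd.DataFrame(values, columns=columns) if columns else pd.DataFrame(values)
    return QuantMatrix(df, **kw)
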