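import numpy as np
import pandas as pd
import pytest

from metaborisk.qc import (FLAG_BELOW_LLOQ, FLAG_BELOW_LOD, FLAG_MISSING_IS,
                           FLAG_OK, MetaboliteMatrix, PanelSpec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_panel():
    """Three-metabolite targeted panel with one semiquantified compound."""
    table = pd.DataFrame({
        "platform": "targeted",
        "metabolite_class": ["amino acid", "GPL", "amino acid"],
        "quantification": ["quantified", "semiquantified", "quantified"],
        "unconfirmed": False,
    }, index=pd.Index(["Glu", "PC_1", "Val"], name="metabolite"))
    limits = pd.DataFrame({
        "metabolite": ["Glu", "PC_1", "Val"],
        "batch": ["all", "all", "all"],
        "lod": [0.1, 0.05, 0.1],
        "lloq": [0.2, 0.05, 0.2],
        "uloq": [100.0, np.nan, 100.0],
    })
    return PanelSpec(table, limits)


@pytest.fixture
def flagged_matrix(small_panel):
    values = pd.DataFrame({
        "Glu": [0.05, 3.7, 150.0, 1.0],
        "PC_1": [0.01, 0.5, 0.9, 1.2],
        "Val": [2.0, 2.0, np.nan, 5.0],
    }, index=[f"s{i}" for i in range(4)])
    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=values.columns,
                         dtype=np.int8)
    flags.loc["s0", "Glu"] = FLAG_BELOW_LLOQ
    flags.loc["s2", "Glu"] = 3  # FLAG_ABOVE_ULOQ
    flags.loc["s0", "PC_1"] = FLAG_BELOW_LOD
    flags.loc["s2", "Val"] = FLAG_MISSING_IS
    return MetaboliteMatrix(values, flags)
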