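import numpy as np
import pandas as pd
import pytest

import xsilence as xs


@pytest.fixture(scope="session")
def default_design():
    return xs.SimulationDesign(seed=11)


@pytest.fixture(scope="session")
def truth300(default_design):
    return xs.simulate_truth(300, default_design)


@pytest.fixture(scope="session")
def counts300(truth300, default_design):
    m, sheet = xs.simulate_chrrna_counts(truth300, default_design, xist_row=True)
    return m, sheet


@pytest.fixture()
def toy_matrix():
    """Two genes, two samples, hand-checkable counts."""
    genes = pd.Index(["gA", "gB"], name="gene_id")
    cols = ["s1", "s2"]
    total = pd.DataFrame([[100, 200], [50, 80]], index=genes, columns=cols)
    xi = pd.DataFrame([[20, 10], [10, 20]], index=genes, columns=cols)
    xa = pd.DataFrame([[20, 30], [10, 20]], index=genes, columns=cols)
    return xs.AllelicCountMatrix(total, xi, xa)
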