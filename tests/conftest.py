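import numpy as np
import pandas as pd
import pytest

from hybridreg.de import CountMatrix


@pytest.fixture
def two_group_design():
    rows = []
    for g in ("P1", "P2"):
        for r in (1, 2, 3):
            rows.append({"sample": f"{g}_{r}", "group": g, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture
def small_count_matrix(two_group_design):
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(50, 500, size=(30, 6)),
        index=[f"g{i}" for i in range(30)],
        columns=two_group_design.index,
    )
    return CountMatrix(counts, two_group_design)
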