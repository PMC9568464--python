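import numpy as np
import pandas as pd
import pytest

from informedbf.priors import expert_registry


@pytest.fixture(scope="session")
def registry():
    return expert_registry()


@pytest.fixture(scope="session")
def toy_correlation_table():
    """Ten rows exercising every filtering rule: 2 perfect correlations,
    one n=5, one n=600, one n1 != n2; five rows survive."""
    return pd.DataFrame(
        {
            "study_id": [f"s{i}" for i in range(10)],
            "r": [1.0, -1.0, 0.3, 0.5, -0.2, 0.1, 0.0, 0.9, 0.45, -0.6],
            "n1": [50, 60, 5, 600, 40, 30, 25, 100, 80, 200],
            "n2": [50, 60, 5, 600, 50, 30, 25, 100, 80, 200],
        }
    )


@pytest.fixture(scope="session")
def toy_bf_table():
    """3 priors x 4 studies with hand-checkable Bayes factors."""
    rows = []
    bfs = {
        "A": [2.0, 0.5, 3.0, 0.2],
        "B": [4.0, 2.0, 5.0, 0.9],
        "C": [2.0, 0.5, 3.0, 0.2],
    }
    for label, vals in bfs.items():
        for i, bf in enumerate(vals):
            rows.append(
                {
                    "study_id": f"s{i}",
                    "prior_label": label,
                    "log_bf10": np.log(bf),
                    "bf10": bf,
                }
            )
    return pd.DataFrame(rows)
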