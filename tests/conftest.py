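import pandas as pd
import pytest

from methnet import syndata


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic input bundle shared across tests (read-only)."""
    return syndata.simulate_bundle(seed=11)


@pytest.fixture(scope="session")
def small_sheet():
    """Minimal 4v4 sample sheet for hand-checkable fits."""
    rows = []
    for g, n in (("case", 4), ("control", 4)):
        for i in range(n):
            rows.append(
                {"sample_id": f"{g}{i}", "group": g,
                 "age": 60.0 + 2 * i, "sex": "F" if i % 2 else "M"}
            )
    return pd.DataFrame(rows).set_index("sample_id")
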