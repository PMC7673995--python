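import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drugcombo.panel import MonotherapyPanel, Treatment

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_panel(values: dict, ses=0.01, orientation="viability") -> MonotherapyPanel:
    """Build a panel from {(drug, conc): [per-line viabilities]}.

    Lines are named L0, L1, ...; ``ses`` may be a scalar or a matching dict.
    """
    cols = pd.MultiIndex.from_tuples(
        [(d, float(c)) for d, c in values], names=["drug", "concentration_uM"]
    )
    n = len(next(iter(values.values())))
    index = pd.Index([f"L{i}" for i in range(n)], name="cell_line")
    means = pd.DataFrame(
        np.column_stack([np.asarray(v, float) for v in values.values()]),
        index=index, columns=cols,
    )
    if isinstance(ses, dict):
        se_frame = pd.DataFrame(
            np.column_stack([np.asarray(ses[k], float) for k in values]),
            index=index, columns=cols,
        )
    else:
        se_frame = pd.DataFrame(float(ses), index=index, columns=cols)
        se_frame[means.isna()] = np.nan
    return MonotherapyPanel(means, se_frame, orientation)


@pytest.fixture
def two_drug_panel() -> MonotherapyPanel:
    """3 lines x 2 drugs with hand-checkable viabilities."""
    return make_panel({("A", 1.0): [0.5, 0.8, 0.2], ("B", 1.0): [0.6, 0.3, 0.9]})


@pytest.fixture
def treatment_ab() -> Treatment:
    return Treatment((("A", 1.0), ("B", 1.0)))
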