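import numpy as np
import pandas as pd
import pytest

import alloatlas as aa
from alloatlas._utils import set_state


@pytest.fixture(scope="session")
def ruleset():
    return aa.default_ruleset()


@pytest.fixture(scope="session")
def panel():
    return aa.default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort (2/group, ~1000 cells/ROI) shared across tests."""
    cfg = aa.default_cohort_config({"NR": 2, "TCMR": 2, "CR": 2}, cells_per_roi=1000, seed=11)
    return aa.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_assignment(small_cohort, ruleset):
    table, _ = small_cohort
    std = aa.preprocess(table)
    return std, aa.assign_phenotypes(std, ruleset)


def make_table(x, y, labels=None, roi="r0", group="NR", patient="p0", markers=("M1",)):
    """Tiny hand-built cell table for geometric tests."""
    n = len(x)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "roi": roi,
            "patient": patient,
            "group": group,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
        }
    )
    for m in markers:
        df[m] = 0.0
    set_state(df, "standardized")
    if labels is None:
        return df
    return df, pd.Series(list(labels), index=df.index, name="final")
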