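import numpy as np
import pandas as pd
import pytest

import dbmtransit as dt


def make_panel(state_paths, covariates=None, round_ages=(1, 5, 8, 12, 15)):
    """Long-format panel from a list of per-subject state sequences."""
    rows = []
    for i, path in enumerate(state_paths):
        sid = f"S{i + 1:04d}"
        for r, state in enumerate(path, start=1):
            row = {
                "subject_id": sid,
                "cohort": "YC",
                "round": r,
                "age_years": float(round_ages[r - 1]),
                "state": state,
            }
            if covariates:
                row.update({k: v[i] for k, v in covariates.items()})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort from the default study conditions, pre-attrition."""
    cfg = dt.default_config(n_subjects=1500, seed=11)
    panel, truth = dt.simulate_cohort(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def twenty_subject_panel():
    """Small random complete-case panel for exact-oracle checks."""
    rng = np.random.default_rng(42)
    states = np.array(dt.STATES, dtype=object)
    paths = [list(states[rng.integers(0, 4, size=5)]) for _ in range(20)]
    sexes = ["male" if rng.random() < 0.5 else "female" for _ in range(20)]
    return make_panel(paths, covariates={"sex": sexes})
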