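import numpy as np
import pandas as pd
import pytest

from mapt_cea import (TariffTable, TrialConfig, apply_missingness,
                      cost_panel_for, generate_trial)


@pytest.fixture(scope="session")
def small_config():
    return TrialConfig(n_per_arm=120, random_seed=11)


@pytest.fixture(scope="session")
def small_trial(small_config):
    """A complete (no missing data) 480-participant trial."""
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def masked_trial(small_trial, small_config):
    return apply_missingness(small_trial, small_config)


@pytest.fixture(scope="session")
def small_panel(masked_trial):
    return cost_panel_for(masked_trial)


@pytest.fixture(scope="session")
def default_tariffs():
    return TariffTable.from_config()


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_events(records):
    """Build a resource-event frame from (pid, period, category, subcategory,
    quantity, los_days, duration_days) tuples."""
    rows = []
    for rec in records:
        pid, period, cat, sub, qty = rec[:5]
        los = rec[5] if len(rec) > 5 else np.nan
        dur = rec[6] if len(rec) > 6 else np.nan
        rows.append({"participant_id": pid, "period_index": period,
                     "category": cat, "subcategory": sub, "quantity": qty,
                     "length_of_stay_days": los, "drug_code": "",
                     "duration_days": dur})
    return pd.DataFrame(rows)
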