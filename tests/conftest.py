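import pandas as pd
import pytest

from advesig.linelisting import SCHEMA_COLUMNS


def make_listing(rows):
    """Build a schema DataFrame from (drug, reaction_pt, soc, **overrides) dicts."""
    defaults = {
        "soc": "SOC X",
        "age_group": "18-64",
        "sex": "female",
        "route": "i.v.",
        "year": 2018,
        "serious": False,
        "outcome": "recovered",
        "concomitant": "",
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"report_id": f"R{i:04d}", **defaults, **row}
        records.append(rec)
    return pd.DataFrame(records, columns=SCHEMA_COLUMNS)


@pytest.fixture
def listing_two_drugs():
    """10 rows: drug A carries reaction R on 2 rows + 3 other, drug B 1 + 4."""
    rows = (
        [{"drug": "A", "reaction_pt": "R"}] * 2
        + [{"drug": "A", "reaction_pt": "other"}] * 3
        + [{"drug": "B", "reaction_pt": "R"}] * 1
        + [{"drug": "B", "reaction_pt": "other"}] * 4
    )
    return make_listing(rows)


@pytest.fixture
def small_pv_config():
    from advesig.synthetic_data import SyntheticPVConfig

    return SyntheticPVConfig(
        drugs=("A", "B"),
        totals={"A": 500, "B": 500},
        reactions=(("R1", "SOC1"), ("R2", "SOC1"), ("R3", "SOC2")),
        baseline_probs={"R1": 0.2, "R2": 0.4, "R3": 0.3},
        seed=42,
    )
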