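import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hybridmorph import default_config, derive_composites, group_of, simulate_colony
from hybridmorph.phenodata import RAW_MEASUREMENTS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical phenotype frame from terse row dicts.

    Each row supplies ``id`` (default generated), ``sex`` (default F),
    ``ancestry`` (default 0.5) and any measurement values; unspecified
    measurements default to 100.0 (positive, unit-agnostic).  Pass
    ``None`` to make a measurement missing.
    """
    out = []
    for i, row in enumerate(rows):
        rec = {
            "id": row.get("id", f"r{i}"),
            "sex": row.get("sex", "F"),
            "ancestry": row.get("ancestry", 0.5),
        }
        for m in RAW_MEASUREMENTS:
            v = row.get(m, 100.0)
            rec[m] = np.nan if v is None else float(v)
        out.append(rec)
    df = pd.DataFrame(out)
    df.insert(3, "group", group_of(df["ancestry"].to_numpy()))
    return df


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture(scope="session")
def default_colony():
    """One default synthetic colony (134 animals) with its ground truth."""
    colony, truth = simulate_colony(default_config(seed=20240901))
    return derive_composites(colony), truth
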