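import numpy as np
import pandas as pd
import pytest

from sipmet.community import CountTable


def make_table(counts: dict, meta: dict) -> CountTable:
    """Build a CountTable from {sample: [counts]} and {sample: meta dict}."""
    df = pd.DataFrame(counts)
    df.index = [f"OTU_{i + 1}" for i in range(len(df))]
    m = pd.DataFrame.from_dict(meta, orient="index")
    m.index.name = "sample_id"
    return CountTable(df, m)


def composite_meta(sex="F", time_h=4, replicate=1, treatment="13C",
                   fraction_class="heavy", is_control=False) -> dict:
    return {"sex": sex, "time_h": time_h, "treatment": treatment,
            "fraction_class": fraction_class, "replicate": replicate,
            "is_control": is_control}


@pytest.fixture
def four_composite_table():
    """2 OTUs x 4 composites, one replicate: the hand-computed EF example.

    OTU_1 relative abundances are (0.4, 0.2, 0.1, 0.1) across
    (13C heavy, 13C light, 12C heavy, 12C light), so EF = 2 - 1 = 1.
    """
    counts = {
        "c13_heavy": [4, 6], "c13_light": [2, 8],
        "c12_heavy": [1, 9], "c12_light": [1, 9],
    }
    meta = {
        "c13_heavy": composite_meta(treatment="13C", fraction_class="heavy"),
        "c13_light": composite_meta(treatment="13C", fraction_class="light"),
        "c12_heavy": composite_meta(treatment="12C", fraction_class="heavy"),
        "c12_light": composite_meta(treatment="12C", fraction_class="light"),
    }
    return make_table(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)
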