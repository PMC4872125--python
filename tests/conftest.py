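import numpy as np
import pandas as pd
import pytest

from ebprkit.changepoint import OtuTable
from ebprkit.stoichiometry import (
    BatchTimeSeries,
    StoichiometricRatios,
    reference_cycle_ratios,
)


@pytest.fixture(scope="session")
def survey_cycles():
    """The ten published per-cycle ratio sets (4 high + 6 low aeration)."""
    return reference_cycle_ratios()


@pytest.fixture
def simple_cycle():
    """Minimal noiseless cycle: 1 C-mmol/L acetate consumed at VSS 1 g/L."""
    frame = pd.DataFrame(
        {
            "time_min": [0, 60, 120, 180, 240, 300, 360],
            "phase": ["anaerobic"] * 4 + ["aerobic"] * 3,
            "acetate": [1.0, 0.7, 0.3, 0.0, 0.0, 0.0, 0.0],
            "phosphate": [1.0, 1.15, 1.35, 1.5, 1.3, 1.1, 1.0],
            "phb": [0.2, 0.5, 0.8, 1.1, 0.8, 0.5, 0.2],
            "phv": [0.1, 0.13, 0.17, 0.2, 0.17, 0.13, 0.1],
            "glycogen": [2.0, 1.85, 1.65, 1.5, 1.6, 1.7, 1.8],
            "vss": 1.0,
        }
    )
    return BatchTimeSeries(frame)


def make_otu_table(counts, ids=None, taxonomy=None, start="2013-05-29"):
    counts = np.asarray(counts)
    n, s = counts.shape
    ids = ids or [f"otu{i}" for i in range(n)]
    dates = pd.date_range(start, periods=s, freq="7D").strftime("%Y-%m-%d")
    tax = pd.Series(taxonomy or ["k__Bacteria"] * n, index=ids)
    return OtuTable(counts=pd.DataFrame(counts, index=ids, columns=dates), taxonomy=tax)


@pytest.fixture
def tiny_table():
    return make_otu_table(
        [[10, 12, 9, 11, 30, 28, 33, 31, 29, 32],
         [50, 48, 52, 49, 20, 22, 18, 21, 19, 23],
         [40, 40, 39, 40, 50, 50, 49, 48, 52, 45]],
    )
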