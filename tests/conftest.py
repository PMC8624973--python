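import hypothesis
import numpy as np
import pandas as pd
import pytest

from steroidmr.io import SUMSTATS_COLUMNS

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


def make_sumstats(rows):
    """Build a canonical summary-statistics frame from per-variant dicts."""
    defaults = dict(CHR="1", BP=1000, EA="A", OA="G", EAF=0.3, INFO=0.99,
                    BETA=0.1, SE=0.05, P=0.01, N=2000, MAC=500)
    records = []
    for i, row in enumerate(rows):
        rec = {**defaults, "BP": 1000 + i, "SNP": f"rs{i + 1}"}
        rec.update(row)
        records.append([rec[c] for c in SUMSTATS_COLUMNS])
    return pd.DataFrame(records, columns=SUMSTATS_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)
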