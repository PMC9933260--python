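import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methentropy as me

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sheet(rows):
    """rows: (sample_id, tissue, age_months, cell_type, pool_size)."""
    return me.SampleSheet(
        pd.DataFrame(
            rows,
            columns=["sample_id", "tissue", "age_months", "cell_type", "pool_size"],
        )
    )


@pytest.fixture
def sheet_factory():
    return make_sheet


def make_reads(chrom, positions, patterns, prefix="r"):
    """One EpireadRecord per pattern string, all covering `positions`."""
    return [
        me.EpireadRecord(chrom, f"{prefix}{i}", tuple(positions), pat)
        for i, pat in enumerate(patterns)
    ]


@pytest.fixture
def reads_factory():
    return make_reads
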