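import math

import pandas as pd
import pytest

from cistrans.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed-effect simulation reused by several test modules."""
    cfg = SimConfig(
        n_genes=300,
        seed=101,
        mean_log_expression=(math.log(800), 0.7),
        min_mean=300.0,
    )
    return cfg, simulate_counts(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """An all-null simulation for calibration checks."""
    cfg = SimConfig(
        n_genes=2000, seed=202, frac_cis=0, frac_trans=0, frac_both=0, frac_null=1.0
    )
    return cfg, simulate_counts(cfg)


@pytest.fixture
def parental_groups():
    def make(counts: pd.DataFrame) -> pd.Series:
        labels = ["P1" if c.startswith("P1") else "P2" for c in counts.columns]
        return pd.Series(
            pd.Categorical(labels, categories=["P1", "P2"]), index=counts.columns
        )

    return make
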