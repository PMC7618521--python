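import numpy as np
import pandas as pd
import pytest

from betrescue.synthio import SimConfig, simulate_timecourse_counts


@pytest.fixture(scope="session")
def small_timecourse():
    """A small default-condition time course shared across read-only tests."""
    cfg = SimConfig(n_genes=600, seed=11)
    counts, truth = simulate_timecourse_counts(cfg)
    return cfg, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_diff_table(gene_ids, lfc, fdr):
    """Minimal differential-test table for classification tests."""
    return pd.DataFrame(
        {"lfc": lfc, "fdr": fdr, "p_value": fdr, "base_mean": 100.0, "tested": True},
        index=pd.Index(gene_ids, name="gene_id"),
    )
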