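import numpy as np
import pandas as pd
import pytest

from xplatcord.containers import ExpressionMatrix, SampleDesign
from xplatcord.diffexpr import DEResults
from xplatcord.synthdata import SimConfig, generate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=300, frac_de=0.1, n_reps=3, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240703)


def make_de_results(
    gene_ids, log2fc, is_deg, contrast="HD", platform="seq"
) -> DEResults:
    """Hand-assembled DEResults for classification tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    table = pd.DataFrame(
        {
            "base_mean": 10.0,
            "log2fc": log2fc,
            "linear_fc": np.where(
                log2fc == 0, 1.0, np.sign(log2fc) * np.power(2.0, np.abs(log2fc))
            ),
            "p": 0.01,
            "fdr": 0.01,
            "is_deg": np.asarray(is_deg, dtype=bool),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    table["direction"] = np.where(
        table["log2fc"] > 0, "up", np.where(table["log2fc"] < 0, "down", "zero")
    )
    return DEResults(table, contrast, "CA", platform)


@pytest.fixture
def toy_design():
    return SampleDesign.from_conditions(("CA", "HD"), n_reps=3)
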