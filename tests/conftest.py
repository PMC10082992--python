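import numpy as np
import pandas as pd
import pytest

from epimr import SummaryTable, harmonized_from_arrays


def make_table(rows, trait_label="trait", trait_type="continuous"):
    """rows: list of dicts with at least snp/ea/oa/beta/se/p."""
    defaults = {"chrom": "1", "pos": 1, "eaf": np.nan, "n": 10_000, "n_cases": np.nan}
    full = [{**defaults, **r} for r in rows]
    return SummaryTable(pd.DataFrame(full), trait_label, trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_harmonized(rng):
    """A well-behaved 10-SNP harmonized set with beta = 0.4 plus noise."""
    J = 10
    g = rng.uniform(0.05, 0.15, J)
    seg = np.full(J, 0.005)
    seG = rng.uniform(0.008, 0.015, J)
    G = 0.4 * g + rng.normal(0, seG)
    return harmonized_from_arrays(g, seg, G, seG, n_exp=30_000, n_out=30_000)


@pytest.fixture
def proportional_harmonized():
    """Exactly proportional data: Gamma = 0.5 * gamma, zero heterogeneity."""
    g = np.array([0.05, 0.08, 0.11, 0.14, 0.17])
    return harmonized_from_arrays(g, np.full(5, 0.004), 0.5 * g, np.full(5, 0.01),
                                  n_exp=20_000, n_out=20_000)
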