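import pandas as pd
import pytest

from foxsplice.config import SimulationConfig
from foxsplice import synthetic


@pytest.fixture(scope="session")
def config():
    """Default study conditions with a fixed seed."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=400, n_ms_genes=120, n_introns=80)


@pytest.fixture(scope="session")
def intron_set(config):
    return synthetic.gen_intron_set(config, "crich", n=200)


def toy_expression_table(rows):
    """Build a small expression table from dicts of column -> value."""
    return pd.DataFrame(rows)


@pytest.fixture
def toy_table():
    """Five genes with known RPKM means and fold scores across two donors."""
    def cols(gene, rpkm, sh3_d1, sh3_d2):
        return {
            "gene_id": gene,
            "rpkm_Donor1_NTC": rpkm, "rpkm_Donor1_Sh3": rpkm, "rpkm_Donor1_Sh5": rpkm,
            "rpkm_Donor2_NTC": rpkm, "rpkm_Donor2_Sh3": rpkm, "rpkm_Donor2_Sh5": rpkm,
            "gfold_Donor1_Sh3": sh3_d1, "gfold_Donor2_Sh3": sh3_d2,
            "gfold_Donor1_Sh5": sh3_d1 / 3, "gfold_Donor2_Sh5": sh3_d2 / 3,
        }
    return toy_expression_table([
        cols("A", 10.0, 0.5, 0.4),
        cols("B", 10.0, -0.5, -0.6),
        cols("C", 10.0, 0.5, -0.5),
        cols("D", 10.0, 0.05, 0.02),
        cols("E", 1.0, 2.0, 2.0),
    ])
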