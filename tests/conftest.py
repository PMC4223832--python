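import numpy as np
import pytest

import spacerscape as ss
from spacerscape.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_ds():
    """An 8-strain, 250 kb simulated dataset exercising every feature class
    except clade blocks and variants (which get dedicated fixtures)."""
    cfg = ss.SimulationConfig(seed=11, n_strains=8, genome_length=250_000)
    return ss.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_ds):
    return run_pipeline(small_ds.genomes, small_ds.metadata, small_ds.genes,
                        small_ds.prophages, small_ds.mge_db)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def make_seq():
    """Factory for seeded random nucleotide sequences."""
    def _make(n: int, seed: int = 0, gc: float = 0.5) -> str:
        r = np.random.default_rng(seed)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(np.array(list("ACGT"))[r.choice(4, size=n, p=p)])
    return _make
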