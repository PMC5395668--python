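import numpy as np
import pandas as pd
import pytest

from sagpipe.synthetic import PangenomeSpec, generate_pangenome


@pytest.fixture(scope="session")
def toy_pangenome():
    """Small seeded pangenome reused across modules: 5 genomes, 10-gene core."""
    spec = PangenomeSpec(
        n_genomes=5,
        core_size=10,
        accessory_pool=30,
        accessory_retention=0.4,
        duplication_rate=0.0,
        genome_length=80_000,
        gene_length=900,
        seed=11,
    )
    return generate_pangenome(spec)


@pytest.fixture()
def toy_matrix_frame():
    """6 genomes x 40 clusters copy-number frame with mixed 0/1/2 entries."""
    rng = np.random.default_rng(42)
    table = rng.choice([0, 1, 1, 1, 2], size=(6, 40))
    return pd.DataFrame(
        table,
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{j:02d}" for j in range(40)],
    )
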