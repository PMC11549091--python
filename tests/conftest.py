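import numpy as np
import pandas as pd
import pytest

from caf_atlas import synthetic
from caf_atlas.core import ExpressionMatrix, LOGNORM
from caf_atlas.rl import LRDatabase


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(
        n_donors=2,
        clusters=[
            synthetic.ClusterSpec("stromal", 30, {"G0010": 2.0, "G0011": 2.0},
                                  lineage="stromal"),
            synthetic.ClusterSpec("tumor", 30, {"G0020": 2.0},
                                  lineage="keratinocyte"),
        ],
        n_genes=400,
        n_chromosomes=2,
        cnv_segments=[synthetic.CNVSegment("chr1", 50, 80, 1.5)],
        malignant_cluster="tumor",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return synthetic.generate_atlas(small_config)


def make_lognorm_matrix(n_cells, n_genes, seed=0, cell_prefix="c"):
    """Random log-normalized-looking matrix with metadata."""
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 1.0, (n_cells, n_genes))
    cells = np.array([f"{cell_prefix}{i}" for i in range(n_cells)], dtype=object)
    genes = np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    meta = pd.DataFrame({
        "donor": [f"D{i % 3}" for i in range(n_cells)],
        "sample": [f"D{i % 3}" for i in range(n_cells)],
        "lineage": "stromal",
        "cluster": ["A" if i < n_cells // 2 else "B" for i in range(n_cells)],
    }, index=list(cells))
    return ExpressionMatrix(values, cells, genes, LOGNORM, meta)


@pytest.fixture()
def toy_db():
    """pairs {(L1,R1)} over 3x3 universes: exact null enumerable (9 outcomes)."""
    return LRDatabase(pairs=[("L1", "R1")],
                      ligand_universe=["L1", "L2", "L3"],
                      receptor_universe=["R1", "R2", "R3"])
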