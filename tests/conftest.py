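import numpy as np
import pytest

import isobayes as ib


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study: 50 genes x 6 samples with known truth."""
    cfg = ib.SimulationConfig(n_genes=50, seed=11)
    genes, parts = ib.simulate_annotation(cfg)
    truth, expr = ib.simulate_expression(parts, cfg)
    counts = ib.simulate_counts(parts, expr, cfg)
    return {"config": cfg, "genes": genes, "partitions": parts, "truth": truth,
            "expression": expr, "counts": counts}


@pytest.fixture
def single_isoform_partition():
    return ib.PseudoExonPartition(
        "g1", "chr1", [(0, 100), (100, 200), (200, 300)],
        np.ones((3, 1), dtype=np.int8), ["i1"],
    )


@pytest.fixture
def two_isoform_partition():
    """Segments (1,2) for isoform a, (2,3) for isoform b: X = [[1,0],[1,1],[0,1]]."""
    return ib.PseudoExonPartition(
        "g2", "chr1", [(0, 100), (100, 200), (200, 300)],
        np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8), ["a", "b"],
    )
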